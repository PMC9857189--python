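"""Synthetic cohort generator.

Emulates the statistical structure the analysis assumes: GC-biased
negative-binomial bin counts, CNV segments diluted by tumor fraction
(depth ratio 1 + tf*(copies-2)/2), a healthy reference cohort, and clinical
outcomes whose hazards depend on planted CNV status. Also provides a
deterministic fixture cohort whose per-gene carrier counts reproduce the
panel's occurring-event frequencies exactly.

All randomness flows from one master seed through named substreams, so each
cohort component regenerates stably.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .depth import DepthProfile, empty_feature_table
from .panel import BinGrid, ClinicalRecord, GenePanelEntry, make_bin_grid
from .survival import DFS, OS, SurvivalOutcome

_STREAMS = {"genome": 0, "controls": 1, "patients": 2, "survival": 3, "clinical": 4}

READ_LENGTH = 100


@dataclass(frozen=True)
class CnvEvent:
    chrom: str
    start: int
    end: int
    copy_state: int  # diploid = 2
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("event start must be < end")
        if self.copy_state < 0 or self.copy_state == 2:
            raise ValueError("copy_state must be a non-diploid nonnegative integer")


@dataclass
class SimConfig:
    seed: int = 0
    n_controls: int = 20
    n_patients: int = 40
    bin_size: int = 100_000
    genome: dict[str, int] | None = None  # None -> derived from the panel
    mean_depth: float = 5.0
    gc_bias: str = "quadratic"  # none | linear | quadratic
    gc_bias_amplitude: float = 0.3
    overdispersion: float = 0.005
    tumor_fraction: float | tuple[float, float] = 0.4
    cnv_events: list[CnvEvent] | None = None  # None -> per-gene events from panel
    event_copies: int = 2  # copies added (AMP) / removed (DEL) for panel events
    dfs_hazard_ratio_per_flag: float = 4.0
    os_hazard_ratio_per_flag: float = 4.0
    flagged_genes: list[str] | None = None  # None -> any planted event flags
    ca125_lognormal: tuple[float, float] = (math.log(300.0), 1.0)
    ca125_cnv_multiplier: float = 3.0
    baseline_dfs_median: float = 30.0
    followup_range: tuple[float, float] = (36.0, 60.0)

    def __post_init__(self) -> None:
        if isinstance(self.tumor_fraction, (int, float)):
            if not 0 <= self.tumor_fraction <= 1:
                raise ValueError("tumor_fraction must be in [0, 1]")
        if self.gc_bias not in {"none", "linear", "quadratic"}:
            raise ValueError(f"unknown gc_bias {self.gc_bias!r}")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")


@dataclass
class SimTruth:
    events_by_patient: dict[str, list[CnvEvent]]
    gene_group: pd.DataFrame  # patients x genes, 0/1
    tumor_fraction: dict[str, float]
    survival_params: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "events_by_patient": {
                pid: [asdict(e) for e in evs]
                for pid, evs in self.events_by_patient.items()
            },
            "gene_group": self.gene_group.to_dict(orient="index"),
            "tumor_fraction": self.tumor_fraction,
            "survival_params": self.survival_params,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class SimCohort:
    grid: BinGrid
    controls: list[DepthProfile]
    patients: list[DepthProfile]
    records: list[ClinicalRecord]
    truth: SimTruth


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream]])


def default_genome(
    panel: Sequence[GenePanelEntry], bin_size: int
) -> dict[str, int]:
    """Chromosome lengths just covering the panel genes (bin-aligned)."""
    ends: dict[str, int] = {}
    for e in panel:
        ends[e.chrom] = max(ends.get(e.chrom, 0), e.end0)
    return {c: int(math.ceil(end / bin_size)) * bin_size
            for c, end in sorted(ends.items())}


def simulate_gc(grid: BinGrid, seed: int) -> BinGrid:
    """Attach plausible per-bin GC fractions (seeded, genome substream)."""
    rng = _rng(seed, "genome")
    gc = np.clip(rng.normal(0.45, 0.07, size=len(grid)), 0.22, 0.75)
    bins = grid.bins.copy()
    bins["gc"] = gc
    return BinGrid(bins=bins, bin_size=grid.bin_size)


def gc_bias_factor(gc: np.ndarray, mode: str, amplitude: float) -> np.ndarray:
    gc = np.asarray(gc, float)
    if mode == "none":
        return np.ones_like(gc)
    if mode == "linear":
        f = 1.0 + amplitude * 2.0 * (gc - 0.5)
    elif mode == "quadratic":
        f = 1.0 - amplitude * (2.0 * (gc - 0.5)) ** 2
    else:
        raise ValueError(f"unknown gc_bias {mode!r}")
    return np.clip(f, 0.05, None)


def panel_events(panel: Sequence[GenePanelEntry], copies: int = 2) -> list[CnvEvent]:
    """One candidate event per panel gene, in the gene's expected direction."""
    events = []
    for e in panel:
        cs = 2 + copies if e.direction == "AMP" else max(0, 2 - copies)
        events.append(CnvEvent(e.chrom, e.start0, e.end0, cs, gene=e.gene_symbol))
    return events


def _event_factor(
    features: pd.DataFrame, events: Sequence[CnvEvent], tf: float
) -> np.ndarray:
    """Expected depth ratio per feature: 1 + tf*(copies-2)/2, pro-rated by
    the fraction of the feature overlapped."""
    factor = np.ones(len(features))
    chrom = features["chrom"].values
    start = features["start"].values
    end = features["end"].values
    length = (end - start).astype(float)
    for ev in events:
        ov = np.minimum(end, ev.end) - np.maximum(start, ev.start)
        mask = (chrom == ev.chrom) & (ov > 0)
        frac = np.zeros(len(features))
        frac[mask] = ov[mask] / length[mask]
        factor += tf * (ev.copy_state - 2) / 2.0 * frac
    return np.clip(factor, 0.0, None)


def simulate_sample(
    cfg: SimConfig,
    template: pd.DataFrame,
    planted: Sequence[CnvEvent],
    tf: float,
    rng: np.random.Generator,
    sample_id: str,
) -> DepthProfile:
    """Draw one sample's per-feature depths.

    Counts per feature ~ negative binomial with mean
    mean_depth * bias(gc) * (1 + tf*(copies-2)/2) * length / read_length.
    """
    if not 0 <= tf <= 1:
        raise ValueError("tumor fraction must be in [0, 1]")
    feats = template.copy()
    length = (feats["end"] - feats["start"]).values.astype(float)
    bias = gc_bias_factor(feats["gc"].values, cfg.gc_bias, cfg.gc_bias_amplitude)
    factor = _event_factor(feats, planted, tf)
    mean_counts = cfg.mean_depth * bias * factor * length / READ_LENGTH
    if cfg.overdispersion > 0:
        lam = rng.gamma(1.0 / cfg.overdispersion,
                        np.maximum(mean_counts, 1e-9) * cfg.overdispersion)
    else:
        lam = mean_counts
    counts = rng.poisson(lam)
    feats["raw_depth"] = counts * READ_LENGTH / length
    feats["norm_depth"] = np.nan
    feats["flag"] = False
    nbins = int((feats["kind"] == "bin").sum())
    total = int(counts[: nbins].sum())
    return DepthProfile(sample_id=sample_id, features=feats, total_reads=total)


def simulate_cohort(
    cfg: SimConfig,
    panel: Sequence[GenePanelEntry] | None = None,
) -> SimCohort:
    """Controls (no CNVs) + patients (planted events) + clinical outcomes.

    Patients carry each candidate event independently with probability equal
    to the gene's occurring-event frequency (or 0.2 for non-gene events).
    DFS/OS times are exponential; the hazard is multiplied by the configured
    ratio for patients whose planted events overlap flagged panel genes.
    """
    panel = list(panel) if panel is not None else []
    genome = cfg.genome or default_genome(panel, cfg.bin_size)
    if not genome:
        raise ValueError("no genome: supply cfg.genome or a gene panel")
    grid = simulate_gc(make_bin_grid(genome, cfg.bin_size), cfg.seed)
    template = empty_feature_table(grid, panel or None)

    candidates = cfg.cnv_events if cfg.cnv_events is not None \
        else panel_events(panel, cfg.event_copies)
    freq_by_gene = {e.gene_symbol: e.occurring_freq for e in panel}

    crng = _rng(cfg.seed, "controls")
    controls = [
        simulate_sample(cfg, template, [], 0.0, crng, f"HC{i + 1:02d}")
        for i in range(cfg.n_controls)
    ]

    prng = _rng(cfg.seed, "patients")
    patients: list[DepthProfile] = []
    events_by_patient: dict[str, list[CnvEvent]] = {}
    tfs: dict[str, float] = {}
    for i in range(cfg.n_patients):
        pid = f"OC{i + 1:02d}"
        if isinstance(cfg.tumor_fraction, tuple):
            tf = float(prng.uniform(*cfg.tumor_fraction))
        else:
            tf = float(cfg.tumor_fraction)
        planted = [ev for ev in candidates
                   if prng.random() < freq_by_gene.get(ev.gene, 0.2)]
        patients.append(simulate_sample(cfg, template, planted, tf, prng, pid))
        events_by_patient[pid] = planted
        tfs[pid] = tf

    gene_names = [e.gene_symbol for e in panel]
    truth_rows = {}
    for pid, planted in events_by_patient.items():
        row = {}
        for g in panel:
            hit = any(
                ev.chrom == g.chrom and ev.end > g.start0 and ev.start < g.end0
                and ((ev.copy_state > 2) == (g.direction == "AMP"))
                for ev in planted
            )
            row[g.gene_symbol] = int(hit)
        truth_rows[pid] = row
    gene_group = pd.DataFrame.from_dict(truth_rows, orient="index",
                                        columns=gene_names).fillna(0).astype(int)

    records = _simulate_clinical(cfg, panel, events_by_patient, gene_group)
    truth = SimTruth(
        events_by_patient=events_by_patient,
        gene_group=gene_group,
        tumor_fraction=tfs,
        survival_params={
            "baseline_dfs_median": cfg.baseline_dfs_median,
            "dfs_hazard_ratio_per_flag": cfg.dfs_hazard_ratio_per_flag,
            "os_hazard_ratio_per_flag": cfg.os_hazard_ratio_per_flag,
            "flagged_genes": cfg.flagged_genes,
        },
    )
    return SimCohort(grid=grid, controls=controls, patients=patients,
                     records=records, truth=truth)


def _simulate_clinical(
    cfg: SimConfig,
    panel: Sequence[GenePanelEntry],
    events_by_patient: dict[str, list[CnvEvent]],
    gene_group: pd.DataFrame,
) -> list[ClinicalRecord]:
    rng = _rng(cfg.seed, "clinical")
    srng = _rng(cfg.seed, "survival")
    flagged = set(cfg.flagged_genes) if cfg.flagged_genes is not None \
        else {e.gene_symbol for e in panel}
    lam_dfs = math.log(2) / cfg.baseline_dfs_median
    mu, sig = cfg.ca125_lognormal
    records = []
    for pid, planted in events_by_patient.items():
        is_flagged = bool(
            gene_group.loc[pid][[g for g in gene_group.columns if g in flagged]].sum()
        ) if len(gene_group.columns) else bool(planted)
        hr_d = cfg.dfs_hazard_ratio_per_flag if is_flagged else 1.0
        hr_o = cfg.os_hazard_ratio_per_flag if is_flagged else 1.0
        dfs_raw = srng.exponential(1.0 / (lam_dfs * hr_d))
        os_raw = dfs_raw + srng.exponential(1.0 / (lam_dfs * hr_o))
        censor = srng.uniform(*cfg.followup_range)
        dfs_m = min(dfs_raw, censor)
        os_m = min(os_raw, censor)
        ca125 = float(np.exp(rng.normal(mu, sig)))
        if planted:
            ca125 *= cfg.ca125_cnv_multiplier
        stage = rng.choice(["I", "II", "III", "IV"], p=[9 / 40, 2 / 40, 26 / 40, 3 / 40])
        hist = rng.choice(
            ["HGSC", "LGSC", "mucinous", "endometrioid", "clear_cell"],
            p=[23 / 40, 3 / 40, 5 / 40, 4 / 40, 5 / 40],
        )
        brca = rng.choice(["pathogenic", "wild_type"], p=[6 / 40, 34 / 40])
        records.append(ClinicalRecord(
            patient_id=pid,
            ca125=max(ca125, 1.0),
            figo_stage=str(stage),
            histology=str(hist),
            dfs_months=round(max(dfs_m, 0.1), 2),
            dfs_event=int(dfs_raw <= censor),
            os_months=round(max(os_m, 0.1), 2),
            os_event=int(os_raw <= censor),
            brca_status=str(brca),
        ))
    return records


def simulate_survival(
    groups: Mapping[str, int],
    hazard_ratio: float,
    seed: int,
    endpoint: str = DFS,
    baseline_median: float = 24.0,
    followup_range: tuple[float, float] = (36.0, 60.0),
) -> list[SurvivalOutcome]:
    """Exponential survival times for labelled patients: carriers (group 1)
    have their hazard multiplied by ``hazard_ratio``; censoring uniform over
    the follow-up window."""
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    rng = np.random.default_rng(seed)
    lam = math.log(2) / baseline_median
    outcomes = []
    for pid, g in groups.items():
        raw = rng.exponential(1.0 / (lam * (hazard_ratio if g else 1.0)))
        censor = rng.uniform(*followup_range)
        outcomes.append(SurvivalOutcome(
            patient_id=pid,
            time=max(min(raw, censor), 1e-3),
            event=int(raw <= censor),
            endpoint=endpoint,
        ))
    return outcomes


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def make_fixture_cohort(
    panel: Sequence[GenePanelEntry],
    n_patients: int = 40,
    seed: int = 17,
) -> tuple[pd.DataFrame, list[ClinicalRecord]]:
    """Deterministic fixture: per-gene carrier counts equal
    round(occurring_freq * n_patients) exactly, assigned to seeded
    pseudo-random patients; the clinical table mirrors the study cohort's
    composition (stages 9/2/26/3, histology 23/3/5/4/5, 20 recurrences,
    6 BRCA-pathogenic, CA125 median 575.5, 3 patients lost to OS follow-up).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    for e in panel:
        if e.occurring_freq > 1:
            raise ValueError(f"{e.gene_symbol}: frequency > 1")
    rng = np.random.default_rng(seed)
    pids = [f"OC{i + 1:02d}" for i in range(n_patients)]
    groups = pd.DataFrame(0, index=pids, columns=[e.gene_symbol for e in panel])
    for e in panel:
        k = _round_half_up(e.occurring_freq * n_patients)
        if k > 0:
            carriers = rng.choice(pids, size=min(k, n_patients), replace=False)
            groups.loc[carriers, e.gene_symbol] = 1

    def _tiled(counts: dict[str, int]) -> list[str]:
        vals = [v for v, c in counts.items() for _ in range(c)]
        vals += [vals[-1]] * (n_patients - len(vals)) if vals else ["unknown"] * n_patients
        vals = vals[:n_patients]
        rng.shuffle(vals)
        return vals

    scale = n_patients / 40
    stages = _tiled({"I": round(9 * scale), "II": round(2 * scale),
                     "III": round(26 * scale), "IV": round(3 * scale)})
    hists = _tiled({"HGSC": round(23 * scale), "LGSC": round(3 * scale),
                    "mucinous": round(5 * scale), "endometrioid": round(4 * scale),
                    "clear_cell": round(5 * scale)})
    brca = _tiled({"pathogenic": round(6 * scale), "wild_type": n_patients})

    n_rec = round(20 * scale)
    rec_flags = np.zeros(n_patients, dtype=int)
    rec_flags[rng.choice(n_patients, size=n_rec, replace=False)] = 1

    # CA125 lognormal, rescaled so the cohort median is exactly 575.5
    ca = np.exp(rng.normal(math.log(575.5), 1.0, size=n_patients))
    ca *= 575.5 / np.median(ca)

    followup = rng.uniform(37.5, 58.0, size=n_patients).round(1)
    dfs = np.where(rec_flags == 1,
                   np.clip(np.exp(rng.normal(math.log(11.0), 0.5, size=n_patients)),
                           1.0, None).round(1),
                   followup)
    dfs = np.minimum(dfs, followup)

    lost = set(rng.choice(n_patients, size=min(3, max(n_patients - 1, 0)),
                          replace=False)) if n_patients >= 4 else set()
    died = np.zeros(n_patients, dtype=int)
    rec_idx = np.flatnonzero(rec_flags == 1)
    n_died = min(len(rec_idx), round(12 * scale))
    if n_died:
        died[rng.choice(rec_idx, size=n_died, replace=False)] = 1

    records = []
    for i, pid in enumerate(pids):
        if i in lost:
            os_m, os_e = float("nan"), 0
        elif died[i]:
            os_m = round(float(dfs[i] + rng.uniform(2, 20)), 1)
            os_e = 1
        else:
            os_m, os_e = float(max(followup[i], dfs[i])), 0
        records.append(ClinicalRecord(
            patient_id=pid,
            ca125=round(float(ca[i]), 1),
            figo_stage=stages[i],
            histology=hists[i],
            dfs_months=float(dfs[i]),
            dfs_event=int(rec_flags[i]),
            os_months=os_m,
            os_event=os_e,
            brca_status=brca[i],
        ))
    return groups, records
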