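"""Control-referenced Z-scores, threshold CNV calls, directional grouping,
and the genome-wide instability (Gi) score.

Calls use strict thresholds: z > 2 is an amplification, z < -2 a deletion;
exactly +/-2 is neutral. Gi is the sum of |z| over non-missing features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .depth import DepthProfile, NormalizationConfig, loess_gc_normalize, thin_profile
from .panel import GenePanelEntry

logger = logging.getLogger(__name__)

Z_AMP = 2.0
Z_DEL = -2.0

AMP = "AMP"
DEL = "DEL"
NEUTRAL = "NEUTRAL"


@dataclass
class ReferenceModel:
    """Per-feature mean/SD of normalized depth learned from healthy controls.

    SD is the sample SD (n-1) floored at max(1e-6, 0.05*mu): shallow-depth
    Poisson noise implies a coefficient-of-variation floor, and the floor
    prevents infinite Z at zero-variance features.
    """

    feature_ids: list[str]
    kinds: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    n_controls: int

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValueError("reference requires >= 2 controls")
        if len(self.mu) != len(self.feature_ids) or len(self.sigma) != len(self.mu):
            raise ValueError("mu/sigma length mismatch")


@dataclass
class ZProfile:
    """Per-feature Z-scores for one sample (NaN = flagged/missing)."""

    sample_id: str
    table: pd.DataFrame  # columns: feature_id, kind, z

    @property
    def z(self) -> pd.Series:
        return self.table.set_index("feature_id")["z"]


@dataclass
class CnvCall:
    gene_symbol: str
    z: float
    call: str
    group: int


@dataclass
class GiScore:
    sample_id: str
    gi: float
    n_features: int


def sigma_floor(mu: np.ndarray) -> np.ndarray:
    return np.maximum(1e-6, 0.05 * np.asarray(mu, float))


def build_reference(control_profiles: Sequence[DepthProfile]) -> ReferenceModel:
    """Per-feature mean and SD of (normalized) depth across control samples."""
    if len(control_profiles) < 2:
        raise ValueError(f"need >= 2 controls, got {len(control_profiles)}")
    ids0 = control_profiles[0].feature_ids
    for p in control_profiles[1:]:
        if p.feature_ids != ids0:
            raise ValueError(
                f"control {p.sample_id} feature set differs from {control_profiles[0].sample_id}"
            )
    mat = np.column_stack([p.depth_for_scoring.values for p in control_profiles])
    import warnings as _warnings
    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        # features flagged in every control yield all-NaN slices by design
        _warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(mat, axis=1)
        sd = np.nanstd(mat, axis=1, ddof=1)
    n_obs = np.sum(~np.isnan(mat), axis=1)
    mu[n_obs < 2] = np.nan
    sd[n_obs < 2] = np.nan
    sigma = np.where(np.isnan(sd), np.nan, np.maximum(sd, sigma_floor(mu)))
    return ReferenceModel(
        feature_ids=ids0,
        kinds=control_profiles[0].features["kind"].values.copy(),
        mu=mu,
        sigma=sigma,
        n_controls=len(control_profiles),
    )


def zscore(profile: DepthProfile, ref: ReferenceModel) -> ZProfile:
    """z = (normalized depth - mu) / sigma per feature; flagged -> NaN."""
    if profile.feature_ids != ref.feature_ids:
        raise ValueError(
            f"sample {profile.sample_id} feature set does not match the reference"
        )
    depth = profile.depth_for_scoring.values
    with np.errstate(invalid="ignore"):
        z = (depth - ref.mu) / ref.sigma
    table = pd.DataFrame({
        "feature_id": ref.feature_ids,
        "kind": ref.kinds,
        "z": z,
    })
    return ZProfile(sample_id=profile.sample_id, table=table)


def call_cnv(z: float) -> str:
    """AMP iff z > 2, DEL iff z < -2, else NEUTRAL (strict inequalities)."""
    if z is None or np.isnan(z):
        return NEUTRAL
    if z > Z_AMP:
        return AMP
    if z < Z_DEL:
        return DEL
    return NEUTRAL


def group_by_direction(z: float, direction: str) -> int:
    """Directional 0/1 grouping: an AMP-panel gene scores 1 iff z > 2, a
    DEL-panel gene 1 iff z < -2; anything else (incl. missing z) is 0."""
    if direction not in {AMP, DEL}:
        raise ValueError(f"direction must be AMP or DEL, got {direction!r}")
    if z is None or np.isnan(z):
        return 0
    if direction == AMP:
        return int(z > Z_AMP)
    return int(z < Z_DEL)


def calls_for_sample(zp: ZProfile, panel: Sequence[GenePanelEntry]) -> list[CnvCall]:
    """Per-gene CNV calls and directional groups for one sample."""
    zmap = zp.z
    calls = []
    for entry in panel:
        z = float(zmap.get(entry.gene_symbol, np.nan))
        calls.append(CnvCall(
            gene_symbol=entry.gene_symbol,
            z=z,
            call=call_cnv(z),
            group=group_by_direction(z, entry.direction),
        ))
    return calls


def gi_score(zp: ZProfile, kind: str | None = None) -> GiScore:
    """Gi = sum of |z| over non-missing features (optionally one kind only)."""
    table = zp.table if kind is None else zp.table[zp.table["kind"] == kind]
    z = table["z"].values
    ok = ~np.isnan(z)
    if not ok.any():
        raise ValueError(f"{zp.sample_id}: no non-missing features for Gi")
    return GiScore(
        sample_id=zp.sample_id,
        gi=float(np.abs(z[ok]).sum()),
        n_features=int(ok.sum()),
    )


def compare_gi(
    group_a: Sequence[GiScore | float],
    group_b: Sequence[GiScore | float],
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test on Gi scores, two-sided.

    Exact null when combined n <= 20 with no ties, normal approximation with
    continuity correction otherwise. Returns (U statistic, p).
    """
    a = np.array([g.gi if isinstance(g, GiScore) else float(g) for g in group_a])
    b = np.array([g.gi if isinstance(g, GiScore) else float(g) for g in group_b])
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    combined = np.concatenate([a, b])
    if np.ptp(combined) == 0:
        logger.warning("all Gi values tied across both groups; p = 1")
        return float(len(a) * len(b) / 2), 1.0
    ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def downsample_concordance(
    profile: DepthProfile,
    target_fraction: float,
    ref: ReferenceModel,
    seed: int,
    cfg: NormalizationConfig | None = None,
    kind: str = "gene",
) -> float:
    """Pearson r between full-depth and thinned gene Z-scores.

    The profile's depths are binomially thinned to ``target_fraction``,
    renormalized with the same config, rescored against ``ref``, and the
    thinned Z compared with the full-depth Z over ``kind`` features
    (all features when no gene features exist).
    """
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    if target_fraction == 1.0:
        return 1.0
    cfg = cfg or NormalizationConfig()
    full = profile if profile.normalized else loess_gc_normalize(profile, cfg)
    thin = loess_gc_normalize(thin_profile(profile, target_fraction, seed=seed), cfg)
    # rescale thinned depths back to the full-depth scale so Z is comparable
    thin.features["norm_depth"] /= target_fraction
    z_full = zscore(full, ref).table
    z_thin = zscore(thin, ref).table
    mask = z_full["kind"] == kind
    if not mask.any():
        mask = pd.Series(True, index=z_full.index)
    zf = z_full.loc[mask, "z"].values
    zt = z_thin.loc[mask, "z"].values
    ok = ~np.isnan(zf) & ~np.isnan(zt)
    if ok.sum() < 3:
        raise ValueError("too few features with defined Z for correlation")
    r, _ = stats.pearsonr(zf[ok], zt[ok])
    return float(r)


def z_matrix(zprofiles: Sequence[ZProfile]) -> pd.DataFrame:
    """Samples x features Z matrix."""
    return pd.DataFrame(
        {zp.sample_id: zp.z for zp in zprofiles}
    ).T


def call_table(
    zprofiles: Sequence[ZProfile],
    panel: Sequence[GenePanelEntry],
) -> pd.DataFrame:
    """Long-format call table: sample, gene, z, call, group."""
    rows = []
    for zp in zprofiles:
        for c in calls_for_sample(zp, panel):
            rows.append((zp.sample_id, c.gene_symbol, c.z, c.call, c.group))
    return pd.DataFrame(rows, columns=["sample_id", "gene", "z", "call", "group"])
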