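"""Statistical layer: nested regression, gating, noise and burst statistics.

The burst quantities follow the gamma model of bursty protein production: if
an isogenic population's expression is Gamma(a, b) distributed — ``a`` bursts
per protein lifetime, ``b`` proteins per burst — then

* noise                eta^2 = variance / mean^2 = 1/a,
* noise strength       nu    = variance / mean   = b,

so burst frequency is estimated as 1/eta^2 and burst size as nu.  The
identities ``nu = eta^2 * mean`` and ``frequency * size = mean`` hold exactly
for every computed record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .io import CellPopulation, Construct, ValidationError

__all__ = [
    "NestedFitResult",
    "NoiseStats",
    "GateSpec",
    "GateReport",
    "OrientationComparison",
    "nested_regression_ftest",
    "gate_cells",
    "population_noise_stats",
    "plate_correct",
    "orientation_group_compare",
]


# ---------------------------------------------------------------------------
# Nested-regression F-test
# ---------------------------------------------------------------------------


@dataclass
class NestedFitResult:
    """Variance partitioning between a reduced and a full linear model."""

    n: int
    df_reduced: int
    df_full: int
    rss_reduced: float
    rss_full: float
    r2_reduced: float
    r2_full: float
    F: float
    p: float


def _as_design(x, n: int, name: str) -> np.ndarray:
    if x is None:
        return np.empty((n, 0))
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != n:
        raise ValidationError(f"{name}: {x.shape[0]} rows, expected {n}")
    return x


def nested_regression_ftest(
    y: Sequence[float],
    x_reduced,
    x_full,
) -> NestedFitResult:
    """F-test for nested linear regression models (both with intercept).

    ``x_reduced`` (possibly None/empty for the intercept-only model) must be a
    column subset of ``x_full``.  F = ((RSS_r - RSS_f)/d_df) /
    (RSS_f/(n - df_full)), with the p-value from the F distribution on
    (d_df, n - df_full) degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    Xr = _as_design(x_reduced, n, "x_reduced")
    Xf = _as_design(x_full, n, "x_full")
    # Every reduced predictor must literally appear among the full predictors.
    for j in range(Xr.shape[1]):
        if not any(np.array_equal(Xr[:, j], Xf[:, jj]) for jj in range(Xf.shape[1])):
            raise ValidationError("x_reduced is not a subset of x_full")
    df_red = Xr.shape[1] + 1
    df_full = Xf.shape[1] + 1
    delta = df_full - df_red
    if delta == 0:
        raise ValidationError("models have equal degrees of freedom (delta df = 0)")
    if n <= df_full:
        raise ValidationError(f"need n > df_full ({n} <= {df_full})")
    Ar = np.column_stack([np.ones(n), Xr])
    Af = np.column_stack([np.ones(n), Xf])
    if np.linalg.matrix_rank(Af) < df_full:
        raise ValidationError("collinear: full design matrix is rank-deficient")
    tss = float(np.sum((y - y.mean()) ** 2))

    def rss(A: np.ndarray) -> float:
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return float(np.sum((y - A @ coef) ** 2))

    rss_r, rss_f = rss(Ar), rss(Af)
    rss_f = min(rss_f, rss_r)  # guard against round-off inverting the nesting
    denom = rss_f / (n - df_full)
    F = ((rss_r - rss_f) / delta) / denom if denom > 0 else np.inf
    p = float(sps.f.sf(F, delta, n - df_full)) if np.isfinite(F) else 0.0
    p = max(p, np.nextafter(0.0, 1.0))  # keep p in (0, 1]
    return NestedFitResult(
        n=n, df_reduced=df_red, df_full=df_full,
        rss_reduced=rss_r, rss_full=rss_f,
        r2_reduced=1.0 - rss_r / tss if tss > 0 else np.nan,
        r2_full=1.0 - rss_f / tss if tss > 0 else np.nan,
        F=float(F), p=p,
    )


# ---------------------------------------------------------------------------
# Single-cell gating
# ---------------------------------------------------------------------------


@dataclass
class GateSpec:
    """Scatter gate: keep cells within median +- k * MAD on FSC and SSC.

    MAD is scaled by 1.4826 (consistent estimate of sigma for normal data).
    ``mcherry_band`` optionally keeps only the central quantile band of
    mCherry (e.g. 0.90 keeps the middle 90%), reducing extrinsic variation.
    """

    k: float = 2.5
    min_cells: int = 500
    mcherry_band: float | None = None

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValidationError("gate k must be positive")
        if self.mcherry_band is not None and not 0 < self.mcherry_band < 1:
            raise ValidationError("mcherry_band must be in (0, 1)")


@dataclass
class GateReport:
    n_before: int
    n_after: int
    removed_fsc: float
    removed_ssc: float
    removed_mcherry: float


_MAD_SCALE = 1.4826


def _scatter_keep(x: np.ndarray, k: float) -> np.ndarray:
    med = np.median(x)
    mad = _MAD_SCALE * np.median(np.abs(x - med))
    if mad == 0:
        return np.abs(x - med) == 0
    return np.abs(x - med) <= k * mad


def gate_cells(pop: CellPopulation, spec: GateSpec | None = None) -> tuple[CellPopulation, GateReport]:
    """Remove spores and scatter outliers from a cell population.

    Keeps cells within median +- k*MAD on both forward and side scatter
    (spores fall far below the scatter medians and are removed by the same
    rule); optionally also restricts to a central mCherry band.  Raises
    ``ValidationError("over-gated")`` if fewer than ``min_cells`` remain.
    """
    spec = spec or GateSpec()
    if pop.n_cells < spec.min_cells:
        raise ValidationError(
            f"{pop.strain_id}: {pop.n_cells} cells < min_cells {spec.min_cells}"
        )
    keep_fsc = _scatter_keep(pop.fsc, spec.k)
    keep_ssc = _scatter_keep(pop.ssc, spec.k)
    keep = keep_fsc & keep_ssc
    removed_mch = 0.0
    if spec.mcherry_band is not None:
        tail = (1.0 - spec.mcherry_band) / 2.0
        lo, hi = np.quantile(pop.mcherry[keep], [tail, 1.0 - tail])
        keep_mch = (pop.mcherry >= lo) & (pop.mcherry <= hi)
        removed_mch = float(np.mean(~keep_mch & keep))
        keep &= keep_mch
    n_after = int(keep.sum())
    if n_after < spec.min_cells:
        raise ValidationError(
            f"over-gated: {pop.strain_id} retains {n_after} < {spec.min_cells} cells"
        )
    report = GateReport(
        n_before=pop.n_cells,
        n_after=n_after,
        removed_fsc=float(np.mean(~keep_fsc)),
        removed_ssc=float(np.mean(~keep_ssc)),
        removed_mcherry=removed_mch,
    )
    return pop.subset(keep), report


# ---------------------------------------------------------------------------
# Noise statistics
# ---------------------------------------------------------------------------


@dataclass
class NoiseStats:
    """Per-strain single-cell mean/variance and derived burst quantities."""

    strain_id: str
    condition: float
    n_cells: int
    mean: float
    variance: float
    noise: float            # eta^2 = var / mean^2
    noise_strength: float   # nu = var / mean
    burst_frequency: float  # 1 / eta^2
    burst_size: float       # nu
    plate: str | None = None


def population_noise_stats(
    pop: CellPopulation, channel: str = "yfp", plate: str | None = None
) -> NoiseStats:
    """Noise decomposition of one (gated) population.

    Uses the unbiased (n-1) variance.  Requires mean > 0 — a non-positive
    mean indicates background over-subtraction upstream.
    """
    values = getattr(pop, channel)
    if len(values) < 2:
        raise ValidationError(f"{pop.strain_id}: need >= 2 cells")
    mu = float(np.mean(values))
    if mu <= 0:
        raise ValidationError(f"{pop.strain_id}: non-positive mean ({mu})")
    var = float(np.var(values, ddof=1))
    eta2 = var / mu**2
    nu = var / mu
    return NoiseStats(
        strain_id=pop.strain_id,
        condition=pop.condition,
        n_cells=len(values),
        mean=mu,
        variance=var,
        noise=eta2,
        noise_strength=nu,
        burst_frequency=1.0 / eta2,
        burst_size=nu,
        plate=plate,
    )


def plate_correct(
    stats: Mapping[str, Mapping[str, NoiseStats]],
    reference: str,
) -> dict[str, dict[str, NoiseStats]]:
    """Correct between-plate mean shifts using a reference strain.

    ``stats`` maps plate id -> strain id -> :class:`NoiseStats`; the
    reference strain must be present on every plate.  With c_p = (grand mean
    of the reference across plates) / (reference mean on plate p):
    mean' = mean * c_p; noise'^2... the noise eta^2 scales as 1/mean, so
    eta'^2 = eta^2 / c_p; noise strength nu' = eta'^2 * mean' (= eta^2 *
    mean, preserved by construction).  Burst statistics are recomputed from
    the corrected noise quantities.
    """
    for plate, strains in stats.items():
        if reference not in strains:
            raise ValidationError(f"reference strain {reference!r} missing on plate {plate!r}")
    grand = float(np.mean([strains[reference].mean for strains in stats.values()]))
    corrected: dict[str, dict[str, NoiseStats]] = {}
    for plate, strains in stats.items():
        c_p = grand / strains[reference].mean
        corrected[plate] = {}
        for strain, s in strains.items():
            mean = s.mean * c_p
            eta2 = s.noise / c_p
            nu = eta2 * mean
            corrected[plate][strain] = NoiseStats(
                strain_id=s.strain_id,
                condition=s.condition,
                n_cells=s.n_cells,
                mean=mean,
                variance=eta2 * mean**2,
                noise=eta2,
                noise_strength=nu,
                burst_frequency=1.0 / eta2,
                burst_size=nu,
                plate=plate,
            )
    return corrected


# ---------------------------------------------------------------------------
# Orientation-group comparison
# ---------------------------------------------------------------------------


@dataclass
class OrientationComparison:
    """Tandem vs convergent expression comparison with per-group covariates."""

    n_tandem: int
    n_convergent: int
    ranksum_stat: float
    ranksum_p: float
    ks_stat: float
    ks_p: float
    #: group -> covariate -> (spearman rho, p); rho is nan for constant covariates.
    covariate_rho: dict[str, dict[str, tuple[float, float]]]


def orientation_group_compare(
    constructs: Sequence[Construct],
    covariates: Mapping[str, Mapping[str, float]] | None = None,
) -> OrientationComparison:
    """Compare expression between tandem and convergent constructs.

    Runs a two-sided rank-sum (Mann-Whitney) test and a two-sample
    Kolmogorov-Smirnov test on the expression distributions, and reports, per
    orientation group, the Spearman rho (+p) of expression against
    ``intergenic_length`` and any extra covariates supplied as
    ``{name: {gene_id: value}}``.
    """
    groups: dict[str, list[Construct]] = {"tandem": [], "convergent": []}
    for c in constructs:
        if c.orientation in groups and c.expression is not None:
            groups[c.orientation].append(c)
    if not groups["tandem"] or not groups["convergent"]:
        raise ValidationError("both orientation groups must be nonempty")
    x = np.array([c.expression for c in groups["tandem"]])
    z = np.array([c.expression for c in groups["convergent"]])
    mw = sps.mannwhitneyu(x, z, alternative="two-sided", method="asymptotic")
    ks = sps.ks_2samp(x, z)

    cov_rho: dict[str, dict[str, tuple[float, float]]] = {}
    for name, members in groups.items():
        cov_rho[name] = {}
        expr = np.array([c.expression for c in members])
        cols: dict[str, np.ndarray] = {}
        if all(c.intergenic_length is not None for c in members):
            cols["intergenic_length"] = np.array(
                [c.intergenic_length for c in members], dtype=float
            )
        for cov_name, table in (covariates or {}).items():
            vals = [table.get(c.gene_id) for c in members]
            if all(v is not None for v in vals):
                cols[cov_name] = np.array(vals, dtype=float)
        for cov_name, vals in cols.items():
            if np.ptp(vals) == 0 or np.ptp(expr) == 0:
                cov_rho[name][cov_name] = (float("nan"), float("nan"))
            else:
                res = sps.spearmanr(expr, vals)
                cov_rho[name][cov_name] = (float(res.statistic), float(res.pvalue))
    return OrientationComparison(
        n_tandem=len(x),
        n_convergent=len(z),
        ranksum_stat=float(mw.statistic),
        ranksum_p=float(mw.pvalue),
        ks_stat=float(ks.statistic),
        ks_p=float(ks.pvalue),
        covariate_rho=cov_rho,
    )
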