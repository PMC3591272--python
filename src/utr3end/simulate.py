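"""Synthetic-data generators for every input class the pipeline consumes.

Each generator plants a known ground truth (returned alongside the data) so
that the full analysis loop — generate, process, estimate — can be closed in
tests:

* :func:`generate_construct_library` — random-composition cloned 3' end
  sequences with heterogeneous cleavage sites and a planted A/T-content →
  expression effect in a window anchored at the main cleavage site.
* :func:`simulate_plate_timecourses` — logistic growth with
  production-proportional fluorophore accumulation, additive backgrounds,
  multiplicative measurement noise and sparse spike outliers.
* :func:`simulate_race_reads` — 3' RACE reads (12-nt UMI, poly(T) block,
  reverse-complemented transcript 3' end) drawn from a construct's true
  cleavage-site distribution.
* :func:`simulate_cell_population` — gamma-distributed bursty single-cell
  expression with a shared lognormal extrinsic factor and an optional
  low-scatter "spore" subpopulation.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CellPopulation, Construct, TimeCourse, ValidationError

__all__ = [
    "CleavageSiteDistribution",
    "GrowthParams",
    "LibraryTruth",
    "PlateTruth",
    "generate_construct_library",
    "simulate_plate_timecourses",
    "simulate_race_reads",
    "simulate_cell_population",
    "logistic_od",
    "logistic_od_integral",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Truth containers
# ---------------------------------------------------------------------------


@dataclass
class CleavageSiteDistribution:
    """True cleavage-site law for one construct: positions + weights (sum 1)."""

    positions: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.positions) != len(self.weights) or len(self.positions) == 0:
            raise ValidationError("positions/weights length mismatch or empty")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValidationError("cleavage-site weights must sum to 1")

    @property
    def main_site(self) -> int:
        best = self.weights.max()
        return int(self.positions[self.weights == best].min())


@dataclass
class GrowthParams:
    """Logistic growth parameters: OD(t) = K / (1 + ((K-od0)/od0) e^{-rt})."""

    K: float = 1.2          # carrying capacity, OD units
    r: float = 7.7e-5       # per-second rate (~150 min doubling, raffinose medium)
    od0: float = 0.05       # inoculation OD

    def __post_init__(self) -> None:
        if not (self.K > self.od0 > 0) or self.r <= 0:
            raise ValidationError("require K > od0 > 0 and r > 0")


@dataclass
class LibraryTruth:
    """Planted ground truth behind a synthetic library / experiment.

    ``effect_center`` (c*) is the window-center offset in bp relative to the
    main cleavage site (negative = upstream) and ``effect_width`` (w*) the
    window size; expression is beta0 + beta1 * AT-fraction(window) + N(0,
    sigma_e), truncated at 0.
    """

    effect_center: int = -40
    effect_width: int = 30
    beta0: float = 0.0
    beta1: float = 8.0
    sigma_e: float = 0.2
    site_noise: float = 15.0
    seed: int | None = None
    sites: dict[str, CleavageSiteDistribution] = field(default_factory=dict)
    window_at: dict[str, float] = field(default_factory=dict)
    growth: GrowthParams = field(default_factory=GrowthParams)
    production: dict[str, float] = field(default_factory=dict)
    bursts: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.effect_width < 1:
            raise ValidationError("effect_width must be >= 1")
        for strain, (a, b) in self.bursts.items():
            if a <= 0 or b <= 0:
                raise ValidationError(f"{strain}: burst parameters must be positive")


@dataclass
class PlateTruth:
    """Ground truth for a simulated plate: rates, growth, planted spikes."""

    production: dict[str, float]
    p_ref: float
    growth: GrowthParams
    backgrounds: dict[str, float]
    #: (well_id, channel, point index) of every injected spike outlier.
    spikes: list[tuple[str, str, int]]


# ---------------------------------------------------------------------------
# Construct library with a planted A/T effect
# ---------------------------------------------------------------------------


def generate_construct_library(
    n: int = 85,
    *,
    effect_center: int = -40,
    effect_width: int = 30,
    beta0: float = 0.0,
    beta1: float = 8.0,
    sigma_e: float = 0.2,
    at_background: float = 0.5,
    site_noise: float = 15.0,
    min_length: int = 200,
    max_length: int = 1000,
    seed=None,
) -> tuple[list[Construct], LibraryTruth]:
    """Generate ``n`` cloned 3' end constructs with a planted A/T effect.

    Each construct gets a random-composition sequence (background A/T fraction
    ``at_background``, split evenly between A and T), a main cleavage site
    plus 0-3 satellite sites with discretised-normal jitter (sd
    ``site_noise``), and an expression value driven by the *realised* A/T
    fraction of the ``effect_width``-bp window centred ``effect_center`` bp
    from the main site.  Per-construct A/T levels of the planted window are
    spread over [0.1, 0.9] (a jittered stratification, so every library
    covers the compositional range), which makes expression span a wide,
    continuous range (> 10-fold at the defaults).

    Returns the constructs (with ``cleavage_site`` set to the true main site
    and ``expression`` attached) and a :class:`LibraryTruth`.
    """
    if n < 3:
        raise ValidationError("need n >= 3 constructs")
    rng = _rng(seed)
    truth = LibraryTruth(
        effect_center=effect_center,
        effect_width=effect_width,
        beta0=beta0,
        beta1=beta1,
        sigma_e=sigma_e,
        site_noise=site_noise,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )
    half_lo = effect_width // 2
    half_hi = effect_width - half_lo
    # Jittered stratification of the planted window's A/T level.
    levels = 0.1 + 0.8 * (rng.permutation(n) + rng.random(n)) / n
    constructs = []
    for i in range(n):
        gene_id = f"SYN{i + 1:04d}"
        length = int(rng.integers(min_length, max_length + 1))
        while True:
            # Main site must leave the planted window inside the sequence and
            # stay >= 25 bp from the start so that RACE fragments are mappable.
            lo = max(25, half_lo - effect_center, -effect_center - half_lo + 1)
            hi = length - 20
            if lo + 10 < hi and 0 <= lo + effect_center - half_lo:
                break
            length = min(max_length, length + 100)  # regenerate longer, never clip
        site = int(rng.integers(lo, hi))
        win_start = site + effect_center - half_lo
        win_end = site + effect_center + half_hi
        assert 0 <= win_start < win_end <= length

        # Background composition, then overwrite the planted window.
        seq = rng.choice(
            np.array(list("ATGC")),
            size=length,
            p=[at_background / 2, at_background / 2,
               (1 - at_background) / 2, (1 - at_background) / 2],
        )
        u = levels[i]
        is_at = rng.random(win_end - win_start) < u
        at_choice = rng.choice(np.array(list("AT")), size=win_end - win_start)
        gc_choice = rng.choice(np.array(list("GC")), size=win_end - win_start)
        seq[win_start:win_end] = np.where(is_at, at_choice, gc_choice)
        sequence = "".join(seq)

        at_frac = float(np.mean(is_at))
        expression = max(
            0.0, beta0 + beta1 * at_frac + rng.normal(0.0, sigma_e) if sigma_e > 0
            else beta0 + beta1 * at_frac
        )

        # Cleavage heterogeneity: main site + 0-3 satellites.
        n_sat = int(rng.integers(0, 4))
        positions = [site]
        for _ in range(n_sat):
            jitter = int(round(rng.normal(0.0, site_noise))) if site_noise > 0 else 0
            p = int(np.clip(site + jitter, 25, length - 1))
            if p not in positions:
                positions.append(p)
        main_w = float(rng.uniform(0.5, 0.85)) if len(positions) > 1 else 1.0
        weights = [main_w]
        if len(positions) > 1:
            rest = rng.dirichlet(np.ones(len(positions) - 1)) * (1 - main_w)
            weights.extend(rest.tolist())
        dist = CleavageSiteDistribution(np.array(positions), np.array(weights))

        constructs.append(
            Construct(
                gene_id=gene_id,
                sequence=sequence,
                cleavage_site=site,
                orientation="tandem" if rng.random() < 0.5 else "convergent",
                intergenic_length=length,
                expression=expression,
            )
        )
        truth.sites[gene_id] = dist
        truth.window_at[gene_id] = at_frac
    return constructs, truth


# ---------------------------------------------------------------------------
# Plate time courses
# ---------------------------------------------------------------------------


def logistic_od(t: np.ndarray, g: GrowthParams) -> np.ndarray:
    """Logistic OD(t) = K / (1 + ((K - od0)/od0) e^{-rt})."""
    t = np.asarray(t, dtype=float)
    return g.K / (1.0 + (g.K - g.od0) / g.od0 * np.exp(-g.r * t))


def logistic_od_integral(t: np.ndarray, g: GrowthParams) -> np.ndarray:
    """Closed-form integral of logistic OD from 0 to t."""
    t = np.asarray(t, dtype=float)
    return (g.K / g.r) * np.log((g.K - g.od0 + g.od0 * np.exp(g.r * t)) / g.K)


def simulate_plate_timecourses(
    production: dict[str, float],
    *,
    p_ref: float = 1.0,
    growth: GrowthParams | None = None,
    t_total: float = 24 * 3600.0,
    dt: float = 1200.0,
    noise_frac: float = 0.01,
    spike_rate: float = 0.0,
    spike_factor: tuple[float, float] | float = (3.0, 10.0),
    od_background: float = 0.08,
    autofl_yfp: tuple[float, float] = (5.0, 20.0),
    autofl_mcherry: tuple[float, float] = (3.0, 10.0),
    seed=None,
) -> tuple[list[TimeCourse], dict[str, TimeCourse], PlateTruth]:
    """Simulate plate-fluorometer time courses for strains with known rates.

    The generative model inverts the expression measure used downstream:
    OD follows a shared logistic curve; fluorophores accumulate as
    dF/dt = P * OD(t) (no degradation: both reporters are long-lived), so the
    noiseless exponential-phase processing returns ``production[strain]``
    exactly up to trapezoidal integration error.  Measurements add an OD
    offset (media), autofluorescence backgrounds ``a + b * OD(t)`` per
    fluorescence channel, multiplicative Gaussian noise of relative sd
    ``noise_frac``, and — at rate ``spike_rate`` per point — multiplicative
    spike outliers recorded in the returned :class:`PlateTruth`.

    Sampling defaults to every 20 minutes over 24 h.  Background wells are
    returned keyed by role (media blank; YFP-only strain, providing the
    mCherry-channel background; mCherry-only strain, providing the
    YFP-channel background).

    Spike magnitudes are drawn uniformly from the ``spike_factor`` range
    (scalar = fixed factor), mimicking transient plate-reader artefacts
    (bubbles, dust, misreads) whose severity ranges from marginal to gross.
    """
    if any(p <= 0 for p in production.values()):
        bad = [s for s, p in production.items() if p <= 0]
        raise ValidationError(f"non-positive production rate for strains {bad}")
    g = growth or GrowthParams()
    rng = _rng(seed)
    times = np.arange(0.0, t_total + dt / 2, dt)
    od_true = logistic_od(times, g)
    integral = logistic_od_integral(times, g)
    ay0, ay1 = autofl_yfp
    am0, am1 = autofl_mcherry

    spikes: list[tuple[str, str, int]] = []

    def measure(well: str, channel: str, clean: np.ndarray) -> np.ndarray:
        noisy = clean * (1.0 + rng.normal(0.0, noise_frac, size=clean.shape)) \
            if noise_frac > 0 else clean.copy()
        if spike_rate > 0:
            lo, hi = (spike_factor, spike_factor) if np.isscalar(spike_factor) \
                else spike_factor
            hit = np.flatnonzero(rng.random(clean.shape) < spike_rate)
            noisy[hit] *= rng.uniform(lo, hi, size=len(hit))
            spikes.extend((well, channel, int(i)) for i in hit)
        return noisy

    def strain_well(well: str, strain: str, p_yfp: float, p_mch: float,
                    has_cells: bool = True) -> TimeCourse:
        od_clean = od_true + od_background if has_cells else np.full_like(times, od_background)
        od_cells = od_true if has_cells else 0.0
        yfp_clean = p_yfp * integral + ay0 + ay1 * od_cells
        mch_clean = p_mch * integral + am0 + am1 * od_cells
        return TimeCourse(
            well_id=well,
            strain_id=strain,
            times=times,
            od=measure(well, "od", od_clean),
            yfp=measure(well, "yfp", yfp_clean),
            mcherry=measure(well, "mcherry", mch_clean),
        )

    samples = [
        strain_well(f"S{i + 1:02d}", strain, p, p_ref)
        for i, (strain, p) in enumerate(production.items())
    ]
    backgrounds = {
        "media_blank": strain_well("B01", "media", 0.0, 0.0, has_cells=False),
        # YFP-only strain: real YFP signal, autofluorescence only in mCherry.
        "yfp_background_strain": strain_well("B02", "yfp_only", p_ref, 0.0),
        # mCherry-only strain: real mCherry signal, autofluorescence only in YFP.
        "mcherry_background_strain": strain_well("B03", "mcherry_only", 0.0, p_ref),
    }
    truth = PlateTruth(
        production=dict(production),
        p_ref=p_ref,
        growth=g,
        backgrounds={
            "od": od_background,
            "yfp_const": ay0, "yfp_per_od": ay1,
            "mcherry_const": am0, "mcherry_per_od": am1,
        },
        spikes=spikes,
    )
    return samples, backgrounds, truth


# ---------------------------------------------------------------------------
# 3' RACE reads
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_race_reads(
    construct: Construct,
    sites: CleavageSiteDistribution,
    n_reads: int,
    *,
    tail_len: float = 25.0,
    min_tail: int = 18,
    site_noise: float = 0.0,
    error_rate: float = 0.0,
    defect_rate: float = 0.0,
    seed=None,
) -> list[tuple[str, str, str]]:
    """Simulate 3' RACE reads for one construct.

    Each read is ``UMI(12 nt) + T*tail + revcomp(transcript 3' fragment)``:
    the fragment ends at a cleavage site drawn from ``sites`` (plus optional
    per-read discretised-normal jitter of sd ``site_noise``) and covers the
    last 60-100 transcribed bases.  ``tail_len`` is the mean of the geometric
    tail-length law, floored at ``min_tail`` (the poly(T) primer anneals at
    least 18 T's).  With probability ``defect_rate`` a read is emitted with a
    truncated (< 8 nt) tail, mimicking mispriming; ``error_rate`` applies
    uniform substitutions to the transcript-derived part.

    Returns ``(read_id, sequence, description)`` tuples; the description
    records the true sampled site for oracle checks.
    """
    if n_reads < 1:
        raise ValidationError("n_reads must be >= 1")
    rng = _rng(seed)
    seq = construct.sequence
    if np.any(sites.positions < 20):
        raise ValidationError(
            f"{construct.gene_id}: cleavage site < 20 bp from sequence start (unmappable)"
        )
    drawn = rng.choice(sites.positions, size=n_reads, p=sites.weights)
    if site_noise > 0:
        drawn = np.clip(
            drawn + np.round(rng.normal(0.0, site_noise, size=n_reads)).astype(int),
            20, len(seq) - 1,
        )
    frag_lens = rng.integers(60, 101, size=n_reads)
    tails = min_tail + rng.geometric(1.0 / max(tail_len - min_tail, 1.0), size=n_reads)
    defects = rng.random(n_reads) < defect_rate if defect_rate > 0 else np.zeros(n_reads, bool)
    umis = rng.choice(_BASES, size=(n_reads, 12))
    reads = []
    for i in range(n_reads):
        site = int(drawn[i])
        start = max(0, site + 1 - int(frag_lens[i]))
        fragment = seq[start: site + 1]
        insert = _revcomp(fragment)
        if error_rate > 0:
            arr = np.array(list(insert))
            hit = np.flatnonzero(rng.random(len(arr)) < error_rate)
            for j in hit:
                arr[j] = rng.choice(_BASES[_BASES != arr[j]])
            insert = "".join(arr)
        tail = int(tails[i]) if not defects[i] else int(rng.integers(0, 8))
        read_seq = "".join(umis[i]) + "T" * tail + insert
        desc = (
            f"gene={construct.gene_id} true_site={site} tail={tail}"
            f" defect={int(defects[i])}"
        )
        reads.append((f"{construct.gene_id}:read{i}", read_seq, desc))
    return reads


# ---------------------------------------------------------------------------
# Single-cell populations
# ---------------------------------------------------------------------------


def simulate_cell_population(
    a: float,
    b: float,
    n_cells: int = 10_000,
    *,
    extrinsic_cv: float = 0.0,
    spore_frac: float = 0.0,
    strain_id: str = "strain",
    condition: float = 0.1,
    a_ref: float = 20.0,
    b_ref: float = 50.0,
    seed=None,
) -> tuple[CellPopulation, np.ndarray]:
    """Simulate a bursty single-cell population under the gamma burst model.

    YFP per cell is Gamma(shape=a, scale=b) — ``a`` bursts per protein
    lifetime, ``b`` proteins per burst — times a lognormal extrinsic factor of
    unit mean and coefficient of variation ``extrinsic_cv`` shared with the
    mCherry channel (Gamma(a_ref, b_ref)).  Forward/side scatter are
    lognormal.  A fraction ``spore_frac`` of cells form a low-scatter,
    low-fluorescence "spore" cluster.

    Returns the population and a boolean array flagging the true spores.
    """
    if a <= 0 or b <= 0:
        raise ValidationError("burst parameters a, b must be positive")
    if n_cells < 100:
        raise ValidationError("need n_cells >= 100")
    if not 0 <= spore_frac < 0.5:
        raise ValidationError("spore_frac must be in [0, 0.5)")
    rng = _rng(seed)
    yfp = rng.gamma(shape=a, scale=b, size=n_cells)
    mch = rng.gamma(shape=a_ref, scale=b_ref, size=n_cells)
    if extrinsic_cv > 0:
        s2 = np.log1p(extrinsic_cv**2)
        extr = rng.lognormal(mean=-s2 / 2, sigma=np.sqrt(s2), size=n_cells)
        yfp = yfp * extr
        mch = mch * extr
    fsc = rng.lognormal(mean=np.log(1e4), sigma=0.20, size=n_cells)
    ssc = rng.lognormal(mean=np.log(5e3), sigma=0.25, size=n_cells)
    spores = rng.random(n_cells) < spore_frac
    if spores.any():
        fsc[spores] *= 0.3
        ssc[spores] *= 0.3
        yfp[spores] *= 0.1
        mch[spores] *= 0.1
    pop = CellPopulation(
        strain_id=strain_id, condition=condition,
        fsc=fsc, ssc=ssc, yfp=yfp, mcherry=mch,
    )
    return pop, spores
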