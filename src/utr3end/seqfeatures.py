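"""3' end sequence features and their association with expression.

Implements the positional analyses used to dissect what, in a cloned 3' end
sequence, drives reporter expression:

* per-window nucleotide composition anchored at the cleavage site or at the
  first base after the stop codon;
* a window-size x window-offset grid of Pearson correlations between window
  A/T (or G/C) content and expression, with a permutation null for the grid
  maximum;
* mean positional G/C profiles for expression-grouped gene sets;
* k-mer occurrence vs expression (Spearman + permutation p);
* IUPAC degenerate motif scanning (efficiency / positioning elements);
* whole-UTR summary features, with a base-pair-maximisation pairing score as
  a declared proxy for folding energy (an external-energy hook is provided).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from Bio.Data.IUPACData import ambiguous_dna_values

from .io import Construct, ValidationError

__all__ = [
    "WindowContent",
    "ScanGrid",
    "MotifPattern",
    "MotifMatch",
    "UtrFeatures",
    "DEFAULT_WINDOW_SIZES",
    "DEFAULT_OFFSETS",
    "DEFAULT_MOTIFS",
    "window_at_content",
    "feature_expression_scan",
    "scan_permutation_null",
    "grouped_gc_profile",
    "kmer_expression_association",
    "motif_scan",
    "global_utr_features",
    "pairing_score",
]

#: Default correlation-grid geometry: window sizes 10..100 bp, window centers
#: 200 bp upstream to 50 bp downstream of the anchor in 5-bp steps.
DEFAULT_WINDOW_SIZES = tuple(range(10, 101, 10))
DEFAULT_OFFSETS = tuple(range(-200, 51, 5))

_AT = frozenset("AT")
_GC = frozenset("GC")


class WindowContent(NamedTuple):
    fraction: float  # nan when the window lies entirely outside the sequence
    truncated: bool


def window_at_content(
    seq: str, center: int, size: int, anchor_pos: int, feature: str = "at_content"
) -> WindowContent:
    """Base-composition fraction of a window relative to an anchor position.

    The window is half-open ``[anchor + center - size//2, anchor + center +
    ceil(size/2))``.  Windows truncated at the sequence bounds report the
    fraction over the in-bounds part with ``truncated=True``; windows
    entirely outside report ``nan`` (never 0).
    """
    if size < 1:
        raise ValueError("window size must be >= 1")
    bases = _AT if feature == "at_content" else _GC
    start = anchor_pos + center - size // 2
    end = start + size
    lo, hi = max(0, start), min(len(seq), end)
    if lo >= hi:
        return WindowContent(float("nan"), True)
    window = seq[lo:hi]
    frac = sum(1 for b in window if b in bases) / len(window)
    return WindowContent(frac, (lo, hi) != (start, end))


# ---------------------------------------------------------------------------
# Correlation scan grid
# ---------------------------------------------------------------------------


@dataclass
class ScanGrid:
    """Matrix of expression-feature Pearson correlations, size x offset.

    ``r[i, j]`` is the correlation across constructs between the composition
    of the window of size ``window_sizes[i]`` centred at ``center_offsets[j]``
    (bp relative to the anchor; negative = upstream) and expression; entries
    are nan where fewer than 3 constructs contribute or the feature is
    constant.  ``n_used`` tracks contributing-construct counts.
    """

    window_sizes: np.ndarray
    center_offsets: np.ndarray
    anchor: str
    r: np.ndarray
    n_used: np.ndarray

    def peak(self, absolute: bool = False) -> tuple[int, int, float]:
        """(size, offset, r) of the grid maximum (of r, or of \\|r\\|)."""
        metric = np.abs(self.r) if absolute else self.r
        if np.all(np.isnan(metric)):
            raise ValidationError("scan grid is entirely undefined")
        i, j = np.unravel_index(np.nanargmax(metric), metric.shape)
        return int(self.window_sizes[i]), int(self.center_offsets[j]), float(self.r[i, j])

    def max_abs_r(self) -> float:
        return float(np.nanmax(np.abs(self.r)))

    def to_frame(self) -> pd.DataFrame:
        """Long-format (size, offset, r, n_used) table."""
        rows = []
        for i, s in enumerate(self.window_sizes):
            for j, c in enumerate(self.center_offsets):
                rows.append(
                    {"size": int(s), "offset": int(c),
                     "r": self.r[i, j], "n_used": int(self.n_used[i, j])}
                )
        return pd.DataFrame(rows)


def _anchor_position(construct: Construct, anchor: str) -> int | None:
    if anchor == "cleavage_site":
        return construct.cleavage_site
    if anchor == "utr_start":
        return construct.utr_start
    raise ValueError("anchor must be 'cleavage_site' or 'utr_start'")


def _feature_matrix(
    constructs: Sequence[Construct],
    sizes: Sequence[int],
    offsets: Sequence[int],
    anchor: str,
    feature: str,
) -> np.ndarray:
    """(n_constructs, n_sizes * n_offsets) window-composition matrix (nan = absent)."""
    n = len(constructs)
    F = np.full((n, len(sizes) * len(offsets)), np.nan)
    for row, c in enumerate(constructs):
        pos = _anchor_position(c, anchor)
        if pos is None:
            continue
        col = 0
        for s in sizes:
            for off in offsets:
                F[row, col] = window_at_content(c.sequence, off, s, pos, feature).fraction
                col += 1
    return F


def _masked_pearson(F: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Columnwise Pearson r of F against y, honouring per-column nan patterns."""
    M = ~np.isnan(F)
    Ff = np.where(M, F, 0.0)
    yv = y[:, None] * M
    n = M.sum(axis=0).astype(float)
    sx, sy = Ff.sum(axis=0), yv.sum(axis=0)
    sxx, syy = (Ff**2).sum(axis=0), (yv**2).sum(axis=0)
    sxy = (Ff * yv).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx**2
        vary = n * syy - sy**2
        r = cov / np.sqrt(varx * vary)
    r[(n < 3) | (varx <= 0) | (vary <= 0)] = np.nan
    return r, n.astype(int)


def _expressions(constructs: Sequence[Construct], log: bool) -> np.ndarray:
    y = np.array([np.nan if c.expression is None else c.expression for c in constructs])
    if np.isnan(y).any():
        raise ValidationError("every construct needs an expression value for the scan")
    return np.log(y) if log else y


def feature_expression_scan(
    constructs: Sequence[Construct],
    sizes: Sequence[int] = DEFAULT_WINDOW_SIZES,
    offsets: Sequence[int] = DEFAULT_OFFSETS,
    anchor: str = "cleavage_site",
    feature: str = "at_content",
    log_expression: bool = False,
) -> ScanGrid:
    """Correlate window composition with expression over a size x offset grid.

    For each (size, offset) cell, the Pearson r across constructs between the
    window's A/T (or G/C) fraction and expression.  Constructs whose window is
    entirely outside their sequence are dropped from that cell (tracked in
    ``n_used``); truncated windows contribute their truncated fraction.
    """
    usable = [c for c in constructs
              if c.expression is not None and _anchor_position(c, anchor) is not None]
    if len(usable) < 3:
        raise ValidationError("need >= 3 constructs with expression and a defined anchor")
    y = _expressions(usable, log_expression)
    if np.ptp(y) == 0:
        r = np.full((len(sizes), len(offsets)), np.nan)
        n = np.zeros((len(sizes), len(offsets)), dtype=int)
    else:
        F = _feature_matrix(usable, sizes, offsets, anchor, feature)
        r_flat, n_flat = _masked_pearson(F, y)
        r = r_flat.reshape(len(sizes), len(offsets))
        n = n_flat.reshape(len(sizes), len(offsets))
    return ScanGrid(
        window_sizes=np.asarray(sizes), center_offsets=np.asarray(offsets),
        anchor=anchor, r=r, n_used=n,
    )


def scan_permutation_null(
    constructs: Sequence[Construct],
    sizes: Sequence[int] = DEFAULT_WINDOW_SIZES,
    offsets: Sequence[int] = DEFAULT_OFFSETS,
    anchor: str = "cleavage_site",
    feature: str = "at_content",
    n_perm: int = 1000,
    log_expression: bool = False,
    seed=None,
) -> np.ndarray:
    """Null distribution of the grid's max \\|r\\| under expression shuffling.

    Returns ``n_perm`` maxima of \\|r\\| over the whole grid, each computed
    after permuting expression labels across constructs — a family-wise
    calibration for the observed peak.
    """
    usable = [c for c in constructs
              if c.expression is not None and _anchor_position(c, anchor) is not None]
    if len(usable) < 3:
        raise ValidationError("need >= 3 constructs with expression and a defined anchor")
    rng = np.random.default_rng(seed)
    F = _feature_matrix(usable, sizes, offsets, anchor, feature)
    y = _expressions(usable, log_expression)
    maxima = np.empty(n_perm)
    for p in range(n_perm):
        r, _ = _masked_pearson(F, rng.permutation(y))
        maxima[p] = np.nanmax(np.abs(r))
    return maxima


# ---------------------------------------------------------------------------
# Grouped positional G/C profiles
# ---------------------------------------------------------------------------


def grouped_gc_profile(
    constructs: Sequence[Construct],
    low_q: float = 0.2,
    high_q: float = 0.2,
    window: int = 20,
    span: Sequence[int] = tuple(range(-200, 51)),
    anchor: str = "cleavage_site",
) -> dict[str, pd.DataFrame]:
    """Mean positional G/C content for expression-grouped gene sets.

    Genes are split into the bottom ``low_q`` quantile, top ``high_q``
    quantile, and the middle rest by expression; for each offset in ``span``
    the group mean of the G/C fraction in the ``window``-bp centred window is
    reported.  Genes whose window is entirely outside the sequence at an
    offset are excluded there.  Returns ``{"low"|"mid"|"high": DataFrame}``
    with columns offset, mean_gc, n.
    """
    usable = [c for c in constructs
              if c.expression is not None and _anchor_position(c, anchor) is not None]
    y = np.array([c.expression for c in usable])
    lo_cut = np.quantile(y, low_q)
    hi_cut = np.quantile(y, 1.0 - high_q)
    groups = {
        "low": [c for c, v in zip(usable, y) if v <= lo_cut],
        "high": [c for c, v in zip(usable, y) if v >= hi_cut],
    }
    taken = {c.gene_id for g in groups.values() for c in g}
    groups["mid"] = [c for c in usable if c.gene_id not in taken]
    for name, q in (("low", low_q), ("high", high_q)):
        if len(groups[name]) < 5:
            raise ValidationError(
                f"{name} expression group at quantile {q} has "
                f"{len(groups[name])} genes; need >= 5"
            )
    out = {}
    for name, members in groups.items():
        means, ns = [], []
        for off in span:
            vals = []
            for c in members:
                wc = window_at_content(
                    c.sequence, off, window, _anchor_position(c, anchor), "gc_content"
                )
                if not np.isnan(wc.fraction):
                    vals.append(wc.fraction)
            means.append(np.mean(vals) if vals else np.nan)
            ns.append(len(vals))
        out[name] = pd.DataFrame({"offset": list(span), "mean_gc": means, "n": ns})
    return out


# ---------------------------------------------------------------------------
# k-mer association
# ---------------------------------------------------------------------------


def _region_sequence(c: Construct, region: str,
                     window_spec: tuple[int, int] | None) -> str:
    if region == "whole_utr":
        return c.utr_sequence if c.cleavage_site is not None else c.sequence
    if region == "window":
        if window_spec is None or c.cleavage_site is None:
            raise ValidationError("region='window' needs window_spec and a cleavage site")
        center, size = window_spec
        start = c.cleavage_site + center - size // 2
        return c.sequence[max(0, start): max(0, start + size)]
    raise ValueError("region must be 'whole_utr' or 'window'")


def kmer_expression_association(
    constructs: Sequence[Construct],
    k: int,
    region: str = "whole_utr",
    window_spec: tuple[int, int] | None = None,
    n_perm: int = 1000,
    seed=None,
) -> pd.DataFrame:
    """Associate k-mer occurrence counts with expression across constructs.

    For every k-mer (3 <= k <= 8): per-construct occurrence counts (overlaps
    allowed), Spearman rank correlation with expression, and a permutation p
    from ``n_perm`` expression shuffles (family computed jointly, one shuffle
    re-scores all k-mers).  Constructs whose region is shorter than k
    contribute count 0 and are counted in the ``n_short`` attribute of the
    returned frame.  Rows are sorted by \\|rho\\| descending.
    """
    if not 3 <= k <= 8:
        raise ValidationError("k must be in [3, 8]")
    usable = [c for c in constructs if c.expression is not None]
    if len(usable) < 3:
        raise ValidationError("need >= 3 constructs with expression")
    kmers = ["".join(p) for p in product("ACGT", repeat=k)]
    kindex = {km: i for i, km in enumerate(kmers)}
    counts = np.zeros((len(usable), len(kmers)))
    n_short = 0
    for row, c in enumerate(usable):
        seq = _region_sequence(c, region, window_spec)
        if len(seq) < k:
            n_short += 1
            continue
        for i in range(len(seq) - k + 1):
            counts[row, kindex[seq[i: i + k]]] += 1
    y = np.array([c.expression for c in usable])
    # Spearman as Pearson on (tie-averaged) ranks, vectorised over k-mers.
    cr = sps.rankdata(counts, axis=0)
    yr = sps.rankdata(y)
    rho, _ = _masked_pearson(cr, yr)
    rng = np.random.default_rng(seed)
    exceed = np.ones(len(kmers))  # +1 smoothing: p = (1 + #exceed) / (1 + n_perm)
    for _ in range(n_perm):
        perm_rho, _ = _masked_pearson(cr, rng.permutation(yr))
        exceed += (np.abs(perm_rho) >= np.abs(rho)) | np.isnan(rho)
    pvals = exceed / (n_perm + 1)
    df = pd.DataFrame(
        {"kmer": kmers, "total_count": counts.sum(axis=0).astype(int),
         "rho": rho, "pvalue": pvals}
    )
    df = df.reindex(df["rho"].abs().sort_values(ascending=False).index)
    df = df.reset_index(drop=True)
    df.attrs["n_short"] = n_short
    return df


# ---------------------------------------------------------------------------
# Motif scanning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifPattern:
    """A named IUPAC degenerate DNA pattern."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValidationError(f"{self.name}: empty motif pattern")
        for ch in self.pattern:
            if ch not in ambiguous_dna_values:
                raise ValidationError(
                    f"{self.name}: invalid IUPAC code {ch!r} in pattern {self.pattern!r}"
                )


class MotifMatch(NamedTuple):
    name: str
    start: int  # 0-based


#: The two canonical yeast 3'-processing elements: the A/T-rich efficiency
#: element upstream and the A-rich positioning element proximal to the site.
DEFAULT_MOTIFS = (
    MotifPattern("efficiency_element", "TAYRTA"),
    MotifPattern("efficiency_element", "TATATA"),
    MotifPattern("positioning_element", "AAWAAA"),
)


def motif_scan(seq: str, patterns: Sequence[MotifPattern] = DEFAULT_MOTIFS) -> list[MotifMatch]:
    """All exact degenerate matches on the given strand (overlaps allowed)."""
    seq = seq.upper()
    matches = []
    for pat in patterns:
        allowed = [frozenset(ambiguous_dna_values[ch]) for ch in pat.pattern]
        m = len(allowed)
        for start in range(len(seq) - m + 1):
            if all(seq[start + i] in allowed[i] for i in range(m)):
                matches.append(MotifMatch(pat.name, start))
    return sorted(matches)


# ---------------------------------------------------------------------------
# Whole-UTR features
# ---------------------------------------------------------------------------


class UtrFeatures(NamedTuple):
    utr_length: int
    gc_fraction: float
    at_fraction: float
    pairing_score: int
    folding_energy: float | None
    whole_construct: bool  # True when the cleavage site was unknown


def _nussinov_kernel(codes: np.ndarray, min_loop: int) -> int:
    # Codes: A=0, C=1, G=2, T=3.  Pairs when x+y == 3 (A-T, C-G) or
    # x+y == 5 (G-T wobble).
    n = len(codes)
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i, j - 1]
            cj = codes[j]
            for kk in range(i, j - min_loop):
                s = codes[kk] + cj
                if s == 3 or s == 5:
                    left = dp[i, kk - 1] if kk > i else 0
                    inner = dp[kk + 1, j - 1] if kk + 1 <= j - 1 else 0
                    cand = left + 1 + inner
                    if cand > best:
                        best = cand
            dp[i, j] = best
    return int(dp[0, n - 1])


try:  # numba speeds the O(n^3) DP up by ~100x; the pure-python path is a fallback
    from numba import njit

    _nussinov = njit(cache=False)(_nussinov_kernel)
except Exception:  # pragma: no cover
    _nussinov = _nussinov_kernel

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def pairing_score(seq: str, min_loop: int = 3) -> int:
    """Maximum number of base pairs in a nested (pseudoknot-free) fold.

    Dynamic-programming base-pair maximisation over Watson-Crick (A-T, G-C)
    and G-T wobble pairs with a minimum hairpin loop of ``min_loop`` unpaired
    bases.  This is a declared *proxy* for thermodynamic folding stability,
    not a free-energy computation.
    """
    seq = seq.upper()
    if len(seq) <= min_loop + 1:
        return 0
    codes = np.array([_CODE[b] for b in seq], dtype=np.int16)
    return int(_nussinov(codes, min_loop))


def global_utr_features(
    construct: Construct,
    external_energy: Mapping[str, float] | None = None,
) -> UtrFeatures:
    """Length, composition and pairing score of a construct's 3' UTR.

    The UTR is ``[0, cleavage_site]`` inclusive; when the cleavage site is
    unknown, features are computed over the full construct and flagged via
    ``whole_construct``.  ``external_energy`` lets callers plug in externally
    computed folding energies per gene id.
    """
    seq = construct.utr_sequence
    whole = seq is None
    if whole:
        seq = construct.sequence
    n = len(seq)
    gc = sum(1 for b in seq if b in _GC) / n
    at = sum(1 for b in seq if b in _AT) / n
    energy = None
    if external_energy is not None:
        energy = external_energy.get(construct.gene_id)
    return UtrFeatures(
        utr_length=n,
        gc_fraction=gc,
        at_fraction=at,
        pairing_score=pairing_score(seq),
        folding_energy=energy,
        whole_construct=whole,
    )
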