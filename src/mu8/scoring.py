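"""c-score computation and its downstream summaries.

The c-score quantifies how different the reference protein's residue at an
aligned position is from the family, under one biophysical characteristic p:

    cs(p, r) = ( is_ref(p, r) - mean_fam(p, r) ) / sigma_fam(p, r)

where is_ref(p, r) is the index value (or PC1 representative value) of the
reference residue at position r, and mean/sigma are taken over the family's
residues in that alignment column. A large |c| flags a residue whose
characteristic deviates strongly from the family, weighted up in conserved
columns where sigma is small.

Because sigma can be exactly zero in perfectly conserved columns, a small
floor (a fraction of the median positive sigma across the sequence) replaces
zero or near-zero denominators; floored cells are flagged rather than
silently edited.

The characteristic p is either a raw amino-acid index or the first principal
component of all (standardized) indices in one of the six characteristic
classes — a single representative scale per class.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .aaindex import AAINDEX_RESIDUE_ORDER, IndexScale, is_missing
from .alignment import STANDARD_RESIDUES, CroppedAlignment

log = logging.getLogger(__name__)

#: Clamp bound for histograms and stacked-bar display (in sigma units).
SCORE_CAP = 3.0

#: Default sigma-floor fraction of the median positive family sigma.
DEFAULT_SIGMA_FLOOR_FRAC = 0.01


@dataclass(frozen=True)
class IndexProfile:
    """Per reference position: the index value of the reference residue."""

    characteristic_id: str
    values: np.ndarray  # shape (L,), NaN where missing

    @property
    def L(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FamilyColumnStats:
    """Per position: mean, population sd, and count of family index values."""

    characteristic_id: str
    mean: np.ndarray  # NaN when n == 0
    sd: np.ndarray  # NaN when n < 2
    n: np.ndarray  # int counts

    @property
    def L(self) -> int:
        return len(self.mean)


@dataclass(frozen=True)
class CScoreRow:
    """c-scores for one characteristic along the reference sequence."""

    characteristic_id: str
    scores: np.ndarray  # NaN where undefined
    sigma_floored: np.ndarray  # bool flags

    @property
    def L(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class CScoreMatrix:
    """c-scores for an ordered list of characteristics x positions."""

    rows: tuple[CScoreRow, ...]

    @property
    def characteristics(self) -> tuple[str, ...]:
        return tuple(r.characteristic_id for r in self.rows)

    @property
    def L(self) -> int:
        return self.rows[0].L if self.rows else 0

    def row(self, characteristic_id: str) -> CScoreRow:
        for r in self.rows:
            if r.characteristic_id == characteristic_id:
                return r
        raise KeyError(characteristic_id)


@dataclass(frozen=True)
class PCScale:
    """PC1 representative scale for one characteristic class.

    ``loadings`` is a unit-norm derived IndexScale over the 20 residues;
    ``variance_explained`` is lambda_1 / sum(lambda).
    """

    char_class: str
    loadings: IndexScale
    variance_explained: float
    n_indices_used: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.variance_explained <= 1.0 + 1e-12:
            raise ValueError(f"variance_explained {self.variance_explained} outside [0, 1]")


@dataclass(frozen=True)
class ConservationRow:
    """Family variability per position for one characteristic.

    ``raw`` is the family sigma of the characteristic's index values (the
    denominator of the c-score); ``display`` is min-max normalized to [0, 1]
    per row, 0 = fully conserved (bright), 1 = most variable (dark).
    """

    characteristic_id: str
    raw: np.ndarray
    display: np.ndarray


@dataclass(frozen=True)
class ScoreHistogram:
    """40-bin histogram of c-scores on [-3, 3] with clamped-tail tallies."""

    characteristic_id: str
    bin_edges: np.ndarray  # n_bins + 1 edges
    counts: np.ndarray  # int
    n_clamped_low: int
    n_clamped_high: int


@dataclass(frozen=True)
class ScoreFilter:
    """Closed score interval [lo, hi] for one characteristic."""

    characteristic_id: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"filter lo {self.lo} > hi {self.hi}")


def profile_reference(ref_seq: str, scale: IndexScale) -> IndexProfile:
    """Look up the scale value of each reference residue; 'X' or missing -> NaN."""
    vals = np.full(len(ref_seq), np.nan)
    for i, ch in enumerate(ref_seq):
        if ch in STANDARD_RESIDUES:
            v = scale.values[ch]
            if not is_missing(v):
                vals[i] = v
    return IndexProfile(characteristic_id=scale.accession, values=vals)


def family_column_stats(ca: CroppedAlignment, scale: IndexScale,
                        include_reference: bool = False) -> FamilyColumnStats:
    """Mean and population sd of the family's index values per column.

    Gaps, 'X', and residues with a missing scale entry are excluded. A column
    with a single contributing value carries its mean but no sd; an empty
    column carries neither. The reference is excluded from the family by
    default.
    """
    if not ca.family_records:
        raise ValueError("cropped alignment has no family records")
    records = ca.records if include_reference else ca.family_records
    lut = np.full(128, np.nan)
    for aa in AAINDEX_RESIDUE_ORDER:
        v = scale.values[aa]
        if not is_missing(v):
            lut[ord(aa)] = v
    codes = np.array(
        [[ord(c) for c in seq] for _, seq in records], dtype=np.int64
    )
    vals = lut[codes]  # (n_records, L), NaN for gaps/X/missing
    n = np.sum(~np.isnan(vals), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nansum(vals, axis=0) / n
        sq = np.nansum((vals - mean) ** 2, axis=0)
        sd = np.sqrt(sq / n)  # population (ddof 0)
        # exactly-constant columns: snap to the value, sd exactly 0 (the
        # two-pass formula otherwise leaves eps-level noise that a sigma
        # floor would wrongly rescue)
        col_min = np.nanmin(vals, axis=0)
        col_max = np.nanmax(vals, axis=0)
    constant = (n >= 1) & (col_min == col_max)
    mean = np.where(constant, col_min, mean)
    sd = np.where(constant, 0.0, sd)
    mean = np.where(n >= 1, mean, np.nan)
    sd = np.where(n >= 2, sd, np.nan)
    return FamilyColumnStats(characteristic_id=scale.accession, mean=mean, sd=sd, n=n)


def c_scores(profile: IndexProfile, stats: FamilyColumnStats,
             sigma_floor_frac: float = DEFAULT_SIGMA_FLOOR_FRAC) -> CScoreRow:
    """Evaluate the c-score along the sequence.

    sigma_eff = max(sigma, floor) with floor = sigma_floor_frac * median of
    the positive sigmas across positions; cells where flooring changed the
    denominator are flagged. Missing inputs propagate NaN.
    """
    if profile.L != stats.L:
        raise ValueError(
            f"length mismatch: profile {profile.L} vs family stats {stats.L}"
        )
    sigma = stats.sd
    positive = sigma[np.isfinite(sigma) & (sigma > 0)]
    if positive.size == 0:
        if not np.any(np.isfinite(sigma)):
            raise ValueError("no family variance information: all sigma missing")
        floor = 0.0
    else:
        floor = sigma_floor_frac * float(np.median(positive))
    floored = np.isfinite(sigma) & (sigma < floor)
    sigma_eff = np.where(floored, floor, sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = (profile.values - stats.mean) / sigma_eff
    scores = np.where(np.isfinite(scores), scores, np.nan)
    n_floored = int(np.sum(floored))
    if n_floored:
        log.info(
            "%s: sigma floored at %.6g for %d position(s)",
            profile.characteristic_id, floor, n_floored,
        )
    return CScoreRow(
        characteristic_id=profile.characteristic_id,
        scores=scores,
        sigma_floored=floored,
    )


def pc1_scale(scales: list[IndexScale], char_class: str | None = None) -> PCScale:
    """First principal component of a class's standardized scales.

    Each scale is a point in 20-dimensional residue space. Scales containing
    missing values are dropped with a warning; at least two usable scales are
    required. Because the inputs are already centered per scale (mean 0
    across residues), the decomposition is of the uncentered second-moment
    matrix X^T X / n. Sign convention: PC1 is oriented to correlate
    positively with the elementwise mean of the inputs; on an exact-zero
    correlation, the largest-magnitude loading is made positive.
    """
    usable = []
    for s in scales:
        if s.n_missing:
            log.warning("pc1_scale: dropping %s (%d missing values)", s.accession, s.n_missing)
        else:
            usable.append(s)
    if len(usable) < 2:
        raise ValueError(f"need >=2 usable scales, got {len(usable)}")
    if char_class is None:
        char_class = usable[0].char_class
    X = np.array([s.as_vector() for s in usable])  # (n, 20)
    M = X.T @ X / X.shape[0]
    eigvals, eigvecs = np.linalg.eigh(M)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    # degenerate (rank-deficient) classes: discard eigenvalue noise so a
    # rank-1 class reports variance_explained exactly 1.0
    if eigvals[0] > 0:
        eigvals[eigvals < 1e-12 * eigvals[0]] = 0.0
    pc1 = eigvecs[:, order[0]]
    total = float(eigvals.sum())
    var_explained = float(eigvals[0] / total) if total > 0 else 0.0
    mean_scale = X.mean(axis=0)
    corr = float(pc1 @ mean_scale)
    if corr < 0:
        pc1 = -pc1
    elif corr == 0 and pc1[int(np.argmax(np.abs(pc1)))] < 0:
        pc1 = -pc1
    loadings = IndexScale(
        accession=f"PC1:{char_class}",
        description=f"first principal component of {len(usable)} {char_class} scales",
        values={aa: float(v) for aa, v in zip(AAINDEX_RESIDUE_ORDER, pc1)},
        char_class=char_class,
    )
    return PCScale(
        char_class=char_class,
        loadings=loadings,
        variance_explained=min(var_explained, 1.0),
        n_indices_used=len(usable),
    )


def conservation_row(stats: FamilyColumnStats) -> ConservationRow:
    """Min-max normalize the family sigma per position into [0, 1].

    A constant-sigma row displays as all 0 (rendered fully conserved);
    missing sigmas propagate.
    """
    raw = stats.sd.astype(float)
    finite = raw[np.isfinite(raw)]
    if finite.size == 0:
        raise ValueError("conservation_row: no finite sigma")
    lo, hi = float(finite.min()), float(finite.max())
    if hi == lo:
        display = np.where(np.isfinite(raw), 0.0, np.nan)
    else:
        display = (raw - lo) / (hi - lo)
    return ConservationRow(characteristic_id=stats.characteristic_id, raw=raw, display=display)


def score_histogram(row: CScoreRow, n_bins: int = 40) -> ScoreHistogram:
    """Histogram of finite c-scores, capped at +/-3 sigma.

    Scores beyond the cap land in the edge bins and are tallied separately
    so no data is silently dropped. Bins are half-open [lo, hi) except the
    last, which is closed.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges = np.linspace(-SCORE_CAP, SCORE_CAP, n_bins + 1)
    finite = row.scores[np.isfinite(row.scores)]
    n_low = int(np.sum(finite < -SCORE_CAP))
    n_high = int(np.sum(finite > SCORE_CAP))
    clamped = np.clip(finite, -SCORE_CAP, SCORE_CAP)
    counts, _ = np.histogram(clamped, bins=edges)
    return ScoreHistogram(
        characteristic_id=row.characteristic_id,
        bin_edges=edges,
        counts=counts,
        n_clamped_low=n_low,
        n_clamped_high=n_high,
    )


def filter_scores(row: CScoreRow, f: ScoreFilter) -> np.ndarray:
    """Boolean mask: True where the score is finite and lo <= score <= hi."""
    s = row.scores
    return np.isfinite(s) & (s >= f.lo) & (s <= f.hi)


@dataclass(frozen=True)
class StackSegment:
    characteristic_id: str
    magnitude: float  # |score| clamped at SCORE_CAP
    raw_score: float


@dataclass(frozen=True)
class PositionStacks:
    position: int  # 1-based
    positive: tuple[StackSegment, ...]
    negative: tuple[StackSegment, ...]


def stack_layout(m: CScoreMatrix) -> list[PositionStacks]:
    """Partition characteristics per position into positive/negative stacks.

    Zero and missing scores are omitted; segment magnitudes are |score|
    clamped at the display cap (raw values preserved alongside); segment
    order is the matrix's fixed characteristic order.
    """
    out: list[PositionStacks] = []
    for i in range(m.L):
        pos: list[StackSegment] = []
        neg: list[StackSegment] = []
        for row in m.rows:
            s = float(row.scores[i])
            if not math.isfinite(s) or s == 0.0:
                continue
            seg = StackSegment(
                characteristic_id=row.characteristic_id,
                magnitude=min(abs(s), SCORE_CAP),
                raw_score=s,
            )
            (pos if s > 0 else neg).append(seg)
        out.append(PositionStacks(position=i + 1, positive=tuple(pos), negative=tuple(neg)))
    return out
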