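"""End-to-end orchestration: from alignment + index scales (+ optional
structure) to the full set of computed artifacts.

Two scoring modes exist. ``pc1`` (the default) represents each of the six
characteristic classes by the first principal component of its standardized
member scales, giving one c-score row per class. ``indices`` scores a
user-chosen list of raw index scales instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._errors import InputFormatError, MappingError
from .aaindex import CLASS_DISPLAY_ORDER, IndexScale, standardize_scale
from .alignment import Alignment, CroppedAlignment, crop_to_reference
from .scoring import (
    CScoreMatrix,
    CScoreRow,
    ConservationRow,
    FamilyColumnStats,
    IndexProfile,
    PCScale,
    ScoreFilter,
    ScoreHistogram,
    c_scores,
    conservation_row,
    family_column_stats,
    pc1_scale,
    profile_reference,
    score_histogram,
    stack_layout,
)
from .structure import (
    CalphaSet,
    ChordBundle,
    FocusRegion,
    ProximityHistogram,
    bundle_chords,
    distance_matrix,
    focus_distances,
    map_structure,
    proximity_histogram,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisResult:
    """Everything a front-end needs, computed over one cropped alignment."""

    cropped: CroppedAlignment
    mode: str  # "pc1" | "indices"
    characteristics: tuple[str, ...]
    matrix: CScoreMatrix
    stats: tuple[FamilyColumnStats, ...]
    conservation: tuple[ConservationRow, ...]
    histograms: tuple[ScoreHistogram, ...]
    stacks: list
    pc_scales: tuple[PCScale, ...] | None
    # structure-dependent parts (None when no PDB given)
    focus: FocusRegion | None = None
    chords: list[ChordBundle] | None = None
    chord_band: tuple[float, float] | None = None
    prox_hist: ProximityHistogram | None = None
    filters: tuple[ScoreFilter, ...] = ()


def select_characteristic_scales(
    scales: list[IndexScale],
    mode: str = "pc1",
    index_accessions: list[str] | None = None,
) -> tuple[list[tuple[str, IndexScale]], tuple[PCScale, ...] | None]:
    """Resolve the scoring mode to (characteristic_id, scale) pairs.

    ``pc1``: one PC1 representative per class present with >= 2 usable
    scales, in the fixed class display order. ``indices``: the named
    accessions, standardized, in the order given.
    """
    if mode == "pc1":
        pairs: list[tuple[str, IndexScale]] = []
        pcs: list[PCScale] = []
        for cls in CLASS_DISPLAY_ORDER:
            members = [s for s in scales if s.char_class == cls]
            usable = []
            for s in members:
                try:
                    usable.append(standardize_scale(s))
                except ValueError as exc:
                    log.warning("dropping %s: %s", s.accession, exc)
            if len(usable) < 2:
                if members:
                    log.warning(
                        "class %s has %d usable scale(s); need >= 2 for PC1, skipped",
                        cls, len(usable),
                    )
                continue
            pc = pc1_scale(usable, char_class=cls)
            pcs.append(pc)
            pairs.append((cls, pc.loadings))
        if not pairs:
            raise InputFormatError("no characteristic class has >= 2 usable scales")
        return pairs, tuple(pcs)
    if mode == "indices":
        if not index_accessions:
            raise InputFormatError("indices mode requires a list of accessions")
        by_acc = {s.accession: s for s in scales}
        missing = [a for a in index_accessions if a not in by_acc]
        if missing:
            raise InputFormatError(f"accessions not found: {missing}")
        return [(a, by_acc[a]) for a in index_accessions], None
    raise InputFormatError(f"unknown mode {mode!r}; use pc1 or indices")


def score_alignment(
    aln: Alignment | CroppedAlignment,
    scales: list[IndexScale],
    mode: str = "pc1",
    index_accessions: list[str] | None = None,
    include_reference_in_family: bool = False,
    sigma_floor_frac: float = 0.01,
    focus: FocusRegion | None = None,
    calpha: CalphaSet | None = None,
    structure_offset: int | None = None,
    d_lo: float = 0.0,
    d_hi: float = 8.0,
    min_seq_separation: int = 0,
    filters: tuple[ScoreFilter, ...] = (),
) -> AnalysisResult:
    """Run the whole analysis; the one entry point the CLI wraps."""
    ca = crop_to_reference(aln)
    pairs, pcs = select_characteristic_scales(scales, mode, index_accessions)

    rows: list[CScoreRow] = []
    stats_list: list[FamilyColumnStats] = []
    cons: list[ConservationRow] = []
    hists: list[ScoreHistogram] = []
    for char_id, scale in pairs:
        # relabel with the display id (the class label in pc1 mode)
        profile = IndexProfile(
            characteristic_id=char_id,
            values=profile_reference(ca.reference_seq, scale).values,
        )
        stats = family_column_stats(ca, scale, include_reference=include_reference_in_family)
        stats = FamilyColumnStats(characteristic_id=char_id, mean=stats.mean,
                                  sd=stats.sd, n=stats.n)
        row = c_scores(profile, stats, sigma_floor_frac=sigma_floor_frac)
        rows.append(row)
        stats_list.append(stats)
        cons.append(conservation_row(stats))
        hists.append(score_histogram(row))
    matrix = CScoreMatrix(rows=tuple(rows))
    stacks = stack_layout(matrix)

    chords = None
    band = None
    prox = None
    if calpha is not None:
        if focus is None:
            raise MappingError("a focus region is required to compute chords")
        sm = map_structure(calpha, ca.reference_seq, offset=structure_offset)
        dm = distance_matrix(calpha, sm)
        fd = focus_distances(dm, focus)
        prox = proximity_histogram(fd)
        chords = bundle_chords(fd, d_lo=d_lo, d_hi=d_hi,
                               min_seq_separation=min_seq_separation, focus=focus)
        band = (d_lo, d_hi)

    return AnalysisResult(
        cropped=ca,
        mode=mode,
        characteristics=tuple(c for c, _ in pairs),
        matrix=matrix,
        stats=tuple(stats_list),
        conservation=tuple(cons),
        histograms=tuple(hists),
        stacks=stacks,
        pc_scales=pcs,
        focus=focus,
        chords=chords,
        chord_band=band,
        prox_hist=prox,
        filters=filters,
    )


def rank_positions_by_total_deviation(matrix: CScoreMatrix) -> np.ndarray:
    """Positions (1-based) ordered by the summed |c| over characteristics.

    This is the ranking an analyst reads off the stacked-bar view: positions
    whose cumulative deviation from the family is largest come first. NaN
    scores contribute 0.
    """
    total = np.zeros(matrix.L)
    for row in matrix.rows:
        total += np.nan_to_num(np.abs(row.scores))
    order = np.argsort(-total, kind="stable")
    return order + 1
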