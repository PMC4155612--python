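"""Visualization bundle: the JSON contract any front-end consumes.

The bundle is self-describing (characteristic order, 1-based positions,
Angstrom distances in ``meta``) and schema-validated via pydantic models;
the equivalent JSON Schema document ships in ``mu8/data/vizbundle.schema.json``.
Numbers are serialized with 6 significant digits; missing values become
``null``.
"""

from __future__ import annotations

import json
import math

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from ._errors import MappingError
from .pipeline import AnalysisResult

_SIG_DIGITS = 6


def _num(x) -> float | None:
    """Round to 6 significant digits; NaN/inf -> None."""
    if x is None:
        return None
    x = float(x)
    if not math.isfinite(x):
        return None
    return float(f"{x:.{_SIG_DIGITS}g}")


def _numlist(arr) -> list[float | None]:
    return [_num(v) for v in np.asarray(arr, dtype=float)]


class Meta(BaseModel):
    model_config = ConfigDict(extra="forbid")
    reference_id: str
    L: int = Field(ge=1)
    characteristic_order: list[str]
    mode: str  # "pc1" | "indices"
    position_base: int = 1
    distance_unit: str = "angstrom"


class HistogramOut(BaseModel):
    model_config = ConfigDict(extra="forbid")
    characteristic_id: str
    bin_edges: list[float]
    counts: list[int]
    n_clamped_low: int = Field(ge=0)
    n_clamped_high: int = Field(ge=0)


class StackSegmentOut(BaseModel):
    model_config = ConfigDict(extra="forbid")
    characteristic_id: str
    magnitude: float = Field(ge=0)
    raw_score: float


class PositionStacksOut(BaseModel):
    model_config = ConfigDict(extra="forbid")
    position: int = Field(ge=1)
    residue: str
    positive: list[StackSegmentOut]
    negative: list[StackSegmentOut]


class ConservationRowOut(BaseModel):
    model_config = ConfigDict(extra="forbid")
    characteristic_id: str
    raw: list[float | None]
    display: list[float | None]


class ChordOut(BaseModel):
    model_config = ConfigDict(extra="forbid")
    target_start: int = Field(ge=1)
    target_end: int = Field(ge=1)
    min_distance: float = Field(ge=0)
    brightness_rank: int = Field(ge=0)


class ProximityHistogramOut(BaseModel):
    model_config = ConfigDict(extra="forbid")
    bin_edges: list[float]
    counts: list[int]


class FocusOut(BaseModel):
    model_config = ConfigDict(extra="forbid")
    start: int = Field(ge=1)
    end: int = Field(ge=1)


class FilterOut(BaseModel):
    model_config = ConfigDict(extra="forbid")
    characteristic_id: str
    lo: float
    hi: float


class VizBundle(BaseModel):
    model_config = ConfigDict(extra="forbid")
    meta: Meta
    histograms: list[HistogramOut]
    stacks: list[PositionStacksOut]
    conservation: list[ConservationRowOut]
    chords: list[ChordOut] | None
    chord_band: list[float] | None
    proximity_histogram: ProximityHistogramOut | None
    focus: FocusOut | None
    filters: list[FilterOut]


def build_viz_bundle(result: AnalysisResult) -> VizBundle:
    """Assemble and validate the bundle from an analysis result.

    Components must all refer to the same cropped alignment; a length
    mismatch names the offending parts.
    """
    L = result.cropped.L
    for name, n in (
        ("c-score matrix", result.matrix.L),
        ("stacks", len(result.stacks)),
    ):
        if n != L:
            raise MappingError(f"assembly error: {name} length {n} != alignment length {L}")
    for row in result.conservation:
        if len(row.raw) != L:
            raise MappingError(
                f"assembly error: conservation row {row.characteristic_id} "
                f"length {len(row.raw)} != alignment length {L}"
            )
    order = list(result.characteristics)
    hist_order = [h.characteristic_id for h in result.histograms]
    cons_order = [c.characteristic_id for c in result.conservation]
    if hist_order != order or cons_order != order:
        raise MappingError(
            "assembly error: characteristic order differs between histograms, "
            "conservation rows, and the score matrix"
        )
    ref_seq = result.cropped.reference_seq
    return VizBundle(
        meta=Meta(
            reference_id=result.cropped.reference_id,
            L=L,
            characteristic_order=order,
            mode=result.mode,
        ),
        histograms=[
            HistogramOut(
                characteristic_id=h.characteristic_id,
                bin_edges=[_num(e) for e in h.bin_edges],
                counts=[int(c) for c in h.counts],
                n_clamped_low=h.n_clamped_low,
                n_clamped_high=h.n_clamped_high,
            )
            for h in result.histograms
        ],
        stacks=[
            PositionStacksOut(
                position=ps.position,
                residue=ref_seq[ps.position - 1],
                positive=[
                    StackSegmentOut(
                        characteristic_id=s.characteristic_id,
                        magnitude=_num(s.magnitude),
                        raw_score=_num(s.raw_score),
                    )
                    for s in ps.positive
                ],
                negative=[
                    StackSegmentOut(
                        characteristic_id=s.characteristic_id,
                        magnitude=_num(s.magnitude),
                        raw_score=_num(s.raw_score),
                    )
                    for s in ps.negative
                ],
            )
            for ps in result.stacks
        ],
        conservation=[
            ConservationRowOut(
                characteristic_id=c.characteristic_id,
                raw=_numlist(c.raw),
                display=_numlist(c.display),
            )
            for c in result.conservation
        ],
        chords=(
            None
            if result.chords is None
            else [
                ChordOut(
                    target_start=ch.target_start,
                    target_end=ch.target_end,
                    min_distance=_num(ch.min_distance),
                    brightness_rank=ch.brightness_rank,
                )
                for ch in result.chords
            ]
        ),
        chord_band=None if result.chord_band is None else [_num(v) for v in result.chord_band],
        proximity_histogram=(
            None
            if result.prox_hist is None
            else ProximityHistogramOut(
                bin_edges=[_num(e) for e in result.prox_hist.bin_edges],
                counts=[int(c) for c in result.prox_hist.counts],
            )
        ),
        focus=(
            None
            if result.focus is None
            else FocusOut(start=result.focus.start, end=result.focus.end)
        ),
        filters=[
            FilterOut(characteristic_id=f.characteristic_id, lo=_num(f.lo), hi=_num(f.hi))
            for f in result.filters
        ],
    )


def export_viz_bundle(result: AnalysisResult) -> str:
    """Serialize the validated bundle as JSON text."""
    return build_viz_bundle(result).model_dump_json(indent=2)


def parse_viz_bundle(text: str) -> VizBundle:
    """Re-validate JSON text against the bundle schema."""
    return VizBundle.model_validate(json.loads(text))


def write_json_schema(path) -> None:
    """Write the bundle's JSON Schema document (for non-Python consumers)."""
    with open(path, "w") as fh:
        json.dump(VizBundle.model_json_schema(), fh, indent=2)


def plot_overview(bundle: VizBundle, path) -> None:
    """Static overview figure: stacked c-score bars over the sequence,
    conservation heat rows, and the score histograms.

    Layout is deterministic given the bundle. When a focus region is set, a
    fourth panel shows its residue glyphs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = bundle.meta.characteristic_order
    cmap = plt.get_cmap("tab10")
    colors = {c: cmap(i % 10) for i, c in enumerate(order)}
    L = bundle.meta.L

    n_rows = 4 if bundle.focus is not None else 3
    heights = [1.2, 2.2, 0.9] + ([0.8] if bundle.focus is not None else [])
    fig, axes = plt.subplots(
        n_rows, 1, figsize=(max(8, L / 25), 2.2 * n_rows),
        gridspec_kw={"height_ratios": heights},
    )
    axes = np.atleast_1d(axes)

    # histograms side by side in the top panel
    ax = axes[0]
    for i, h in enumerate(bundle.histograms):
        edges = np.asarray(h.bin_edges)
        centers = (edges[:-1] + edges[1:]) / 2
        width = 6.5  # horizontal slot per characteristic
        ax.bar(centers / 6 + i * 1.2, h.counts, width=0.14,
               color=colors[h.characteristic_id], label=h.characteristic_id)
    ax.set_yticks([])
    ax.set_title("c-score histograms (capped at +/-3 sd)")
    ax.legend(fontsize=5, ncol=len(order), loc="upper right")

    # stacked bars along the sequence
    ax = axes[1]
    for ps in bundle.stacks:
        base = 0.0
        for seg in ps.positive:
            ax.bar(ps.position, seg.magnitude, bottom=base,
                   color=colors[seg.characteristic_id], width=1.0)
            base += seg.magnitude
        base = 0.0
        for seg in ps.negative:
            ax.bar(ps.position, -seg.magnitude, bottom=base,
                   color=colors[seg.characteristic_id], width=1.0)
            base -= seg.magnitude
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlim(0.5, L + 0.5)
    ax.set_ylabel("stacked |c|")
    ax.set_title("context sequence: stacked c-scores")

    # conservation heat map
    ax = axes[2]
    mat = np.array(
        [[np.nan if v is None else v for v in row.display] for row in bundle.conservation]
    )
    ax.imshow(1.0 - mat, aspect="auto", cmap="gray", vmin=0, vmax=1,
              extent=(0.5, L + 0.5, len(order) - 0.5, -0.5))
    ax.set_yticks(range(len(order)), order, fontsize=5)
    ax.set_xlabel("reference position (1-based)")
    ax.set_title("conservation (dark = variable)")

    if bundle.focus is not None:
        ax = axes[3]
        positions = list(range(bundle.focus.start, bundle.focus.end + 1))
        for x, p in enumerate(positions):
            ax.text(x, 0.5, bundle.stacks[p - 1].residue, ha="center",
                    va="center", fontsize=14, family="monospace")
        ax.set_xlim(-0.5, len(positions) - 0.5)
        ax.set_xticks(range(len(positions)), [str(p) for p in positions], fontsize=6)
        ax.set_yticks([])
        ax.set_title(f"focus {bundle.focus.start}-{bundle.focus.end}")

    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
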