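"""Synthetic inputs with the statistical structure the method assumes.

Three generators cover the pipeline's inputs end-to-end without any
downloads:

* :func:`synth_scales` — correlated random amino-acid index scales in each of
  the six characteristic classes (within-class correlation 0.7, so a single
  dominant principal component exists, as with real index families);
* :func:`synth_family` — a protein family alignment around a random consensus
  with per-position substitution rates, plus a reference that is the
  consensus everywhere except a short implanted anomalous region whose
  residues maximally deviate from the family under the class scales;
* :func:`synth_pdb` — a self-avoiding Ca-only random-walk trace written as
  PDB ATOM records (3.8 A consecutive-Ca steps).

All generators are pure functions of their arguments plus a seed: reruns are
byte-identical. The defaults emulate the scale of a triose-phosphate
isomerase-like study: a 248-residue reference, a family of 200 aligned
homologs, and a 7-residue anomalous region at positions 150-156.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

from .aaindex import AAINDEX_RESIDUE_ORDER, CHAR_CLASSES, IndexScale, standardize_scale
from .alignment import Alignment

#: Within-class correlation of synthetic scales (drives PC1 dominance).
CLASS_RHO = 0.7

_CLASS_TAGS = {
    "alpha_turn_propensity": "ALPH",
    "beta_propensity": "BETA",
    "hydrophobicity": "HYDR",
    "composition": "COMP",
    "physicochemical": "PHYS",
    "other": "OTHR",
}


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of a synthetic family.

    ``conservation`` is the per-position substitution probability (low =
    conserved); scalar values broadcast to all positions. The anomaly is a
    1-based inclusive interval of the reference where residues are implanted
    to deviate from the family; ``strength_sigma`` records the intended
    deviation magnitude in family-sigma units (implantation greedily
    maximizes the deviation, so this is a target, not a cap).
    """

    L: int = 248
    N: int = 200
    conservation: float | tuple[float, ...] = 0.15
    anomaly_start: int = 150
    anomaly_end: int = 156
    strength_sigma: float = 3.0
    gap_column_rate: float = 0.02
    seed: int = 7

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("family size N must be >= 2")
        if not 1 <= self.anomaly_start <= self.anomaly_end <= self.L:
            raise ValueError(
                f"anomaly {self.anomaly_start}:{self.anomaly_end} outside 1..{self.L}"
            )

    def conservation_vector(self) -> np.ndarray:
        if isinstance(self.conservation, (int, float)):
            return np.full(self.L, float(self.conservation))
        v = np.asarray(self.conservation, dtype=float)
        if len(v) != self.L:
            raise ValueError(f"conservation length {len(v)} != L {self.L}")
        return v

    @property
    def anomaly_positions(self) -> tuple[int, ...]:
        return tuple(range(self.anomaly_start, self.anomaly_end + 1))


def synth_scales(n_per_class: int = 5, seed: int = 0) -> list[IndexScale]:
    """Random index scales, ``n_per_class`` in each of the six classes.

    Scales within a class share a latent prototype: scale = sqrt(rho) * z +
    sqrt(1 - rho) * noise with rho = 0.7, so PC1 of each class dominates.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    rng = np.random.default_rng(seed)
    scales: list[IndexScale] = []
    for cls in CHAR_CLASSES:
        proto = rng.standard_normal(20)
        for k in range(n_per_class):
            noise = rng.standard_normal(20)
            vec = math.sqrt(CLASS_RHO) * proto + math.sqrt(1 - CLASS_RHO) * noise
            scales.append(
                IndexScale(
                    accession=f"SYN{_CLASS_TAGS[cls]}{k + 1:03d}",
                    description=f"synthetic {cls} scale {k + 1}",
                    values={aa: float(v) for aa, v in zip(AAINDEX_RESIDUE_ORDER, vec)},
                    char_class=cls,
                )
            )
    return scales


def _designated_scales(scales: list[IndexScale]) -> list[IndexScale]:
    """One standardized representative scale per class (the first of each)."""
    seen: dict[str, IndexScale] = {}
    for s in scales:
        if s.char_class not in seen:
            seen[s.char_class] = standardize_scale(s)
    return list(seen.values())


def synth_family(
    spec: FamilySpec, scales: list[IndexScale] | None = None
) -> tuple[Alignment, tuple[int, ...]]:
    """Generate a family alignment with an implanted anomalous reference region.

    The consensus is uniform over the 20 residues; each family sequence
    substitutes each position independently with its conservation-dependent
    probability (uniform over the other 19 letters). The reference equals
    the consensus except inside the anomaly interval, where each residue is
    greedily chosen to maximize the summed |standardized index deviation|
    from the family column mean over one designated scale per class.

    Extra all-family gap columns (rate ``gap_column_rate``) are inserted
    where the *reference row* carries '-', so cropping removes exactly them
    and reference numbering 1..L is stable; the reference's own residues are
    never gapped.

    Returns the alignment (reference id ``REF``) and the implanted 1-based
    anomaly positions.
    """
    rng = np.random.default_rng(spec.seed)
    letters = np.array(list(AAINDEX_RESIDUE_ORDER))
    sub_p = spec.conservation_vector()

    consensus_idx = rng.integers(0, 20, size=spec.L)
    # family substitution: offset 1..19 from the consensus letter, mod 20
    fam_idx = np.tile(consensus_idx, (spec.N, 1))
    mutate = rng.random((spec.N, spec.L)) < sub_p[None, :]
    offsets = rng.integers(1, 20, size=(spec.N, spec.L))
    fam_idx = np.where(mutate, (fam_idx + offsets) % 20, fam_idx)

    designated = _designated_scales(scales or synth_scales(seed=spec.seed + 1))
    # per-scale lookup table over the canonical letter order
    luts = np.array([[s.values[aa] for aa in AAINDEX_RESIDUE_ORDER] for s in designated])

    ref_idx = consensus_idx.copy()
    for pos in spec.anomaly_positions:
        col = fam_idx[:, pos - 1]
        best_letter, best_dev = int(ref_idx[pos - 1]), -1.0
        for cand in range(20):
            dev = 0.0
            for lut in luts:
                colvals = lut[col]
                mu = float(colvals.mean())
                sd = float(colvals.std())
                sd_eff = sd if sd > 0 else 1e-9
                dev += abs((lut[cand] - mu) / sd_eff)
            if dev > best_dev:
                best_letter, best_dev = cand, dev
        ref_idx[pos - 1] = best_letter

    ref_seq = "".join(letters[ref_idx])
    fam_seqs = ["".join(letters[row]) for row in fam_idx]

    # insert reference-gap columns to exercise cropping
    n_insert = rng.binomial(spec.L, spec.gap_column_rate)
    insert_at = np.sort(rng.choice(spec.L + 1, size=n_insert, replace=False))
    ref_row = io.StringIO()
    fam_rows = [io.StringIO() for _ in range(spec.N)]
    ins_ptr = 0
    for col in range(spec.L + 1):
        while ins_ptr < n_insert and insert_at[ins_ptr] == col:
            ref_row.write("-")
            fills = rng.random(spec.N)
            fill_letters = letters[rng.integers(0, 20, size=spec.N)]
            for k in range(spec.N):
                fam_rows[k].write("-" if fills[k] < 0.5 else str(fill_letters[k]))
            ins_ptr += 1
        if col < spec.L:
            ref_row.write(ref_seq[col])
            for k in range(spec.N):
                fam_rows[k].write(fam_seqs[k][col])

    records = [("REF", ref_row.getvalue())] + [
        (f"FAM{k + 1:05d}", fam_rows[k].getvalue()) for k in range(spec.N)
    ]
    aln = Alignment(records=tuple(records), reference_id="REF")
    return aln, spec.anomaly_positions


def synth_pdb(L: int, seed: int = 0, step: float = 3.8,
              min_separation: float = 3.0, max_tries: int = 200,
              sequence: str | None = None) -> str:
    """A self-avoiding Ca-only random-walk trace as PDB text.

    Consecutive Ca atoms sit exactly ``step`` A apart (the backbone
    convention); any pair is at least ``min_separation`` A apart, enforced
    by per-step rejection. Single chain A, resseq 1..L. Residue names follow
    ``sequence`` (one-letter codes) when given, so automatic
    structure-to-sequence mapping works; otherwise all GLY.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    if sequence is not None and len(sequence) != L:
        raise ValueError(f"sequence length {len(sequence)} != L {L}")
    rng = np.random.default_rng(seed)
    coords = [np.zeros(3)]
    while len(coords) < L:
        placed = False
        for _ in range(max_tries):
            v = rng.standard_normal(3)
            v *= step / np.linalg.norm(v)
            cand = coords[-1] + v
            d = np.linalg.norm(np.array(coords[:-1]) - cand, axis=1) if len(coords) > 1 else np.array([np.inf])
            if d.min() >= min_separation:
                coords.append(cand)
                placed = True
                break
        if not placed:
            # back off one step and retry from there
            if len(coords) > 1:
                coords.pop()
            else:
                raise RuntimeError("self-avoiding walk failed; use another seed")
    from Bio.Data.IUPACData import protein_letters_1to3

    lines = []
    for i, c in enumerate(coords, start=1):
        resname = (
            protein_letters_1to3.get(sequence[i - 1], "Unk").upper()
            if sequence
            else "GLY"
        )
        lines.append(
            f"ATOM  {i:5d}  CA  {resname} A{i:4d}    "
            f"{c[0]:8.3f}{c[1]:8.3f}{c[2]:8.3f}{1.00:6.2f}{0.00:6.2f}           C  "
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
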