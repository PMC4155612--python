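"""C-alpha geometry: PDB parsing, sequence mapping, distance matrices,
focus-region proximity, and chord bundling.

Residue proximity is measured between alpha carbons (the standard coarse
proxy; sequence neighbors sit ~3.8 A apart). A *focus region* is a short
contiguous window of the reference sequence (at most 15 residues); its
"sphere of influence" is the set of residues whose Ca lies within a chosen
distance band of the region. Qualifying residues that are sequence-adjacent
are bundled into one chord interval to reduce clutter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from Bio.PDB.Polypeptide import protein_letters_3to1
from scipy.spatial.distance import squareform, pdist

from ._errors import InputFormatError, MappingError

log = logging.getLogger(__name__)

UNMAPPED = -1

#: Default chord distance band (conventional Ca contact cutoff).
DEFAULT_D_LO = 0.0
DEFAULT_D_HI = 8.0

MAX_FOCUS_LEN = 15


@dataclass(frozen=True)
class CalphaSet:
    """Ordered Ca records of one chain: (pdb_resseq, one-letter code, xyz in A)."""

    chain_id: str
    resseqs: tuple[int, ...]
    letters: str
    coords: np.ndarray  # (n, 3) float

    def __post_init__(self) -> None:
        if not all(a < b for a, b in zip(self.resseqs, self.resseqs[1:])):
            raise InputFormatError(f"chain {self.chain_id}: resseq not strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise InputFormatError(f"chain {self.chain_id}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.resseqs)


@dataclass(frozen=True)
class StructureMap:
    """Reference position (1-based) -> index into the CalphaSet, or UNMAPPED."""

    indices: tuple[int, ...]  # length L
    offset: int
    identity: float

    @property
    def L(self) -> int:
        return len(self.indices)

    @property
    def n_mapped(self) -> int:
        return sum(1 for i in self.indices if i != UNMAPPED)


@dataclass(frozen=True)
class FocusRegion:
    """Contiguous 1-based inclusive window of reference positions, <= 15 long."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid focus {self.start}:{self.end}")
        if self.end - self.start + 1 > MAX_FOCUS_LEN:
            raise ValueError(
                f"focus {self.start}:{self.end} longer than {MAX_FOCUS_LEN} residues"
            )

    def positions(self) -> range:
        return range(self.start, self.end + 1)

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ChordBundle:
    """A maximal run of consecutive qualifying residues collapsed to one arch."""

    target_start: int
    target_end: int
    min_distance: float
    brightness_rank: int  # 0 = darkest = closest


def parse_pdb_calpha(path: str | Path, chain: str | None = None) -> CalphaSet:
    """Extract Ca atoms of one chain from a PDB file.

    ``chain=None`` selects the first chain encountered. Altlocs resolve to
    the highest-occupancy conformer (first on ties, which is Bio.PDB's
    ordering). Residues lacking a Ca atom are skipped with a warning; a
    chain without any Ca is an error. Only the first model of multi-model
    files is read; HETATM-only residues are ignored.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure("s", str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise InputFormatError(f"{path}: no models/ATOM records") from None
    chains = {c.id: c for c in model}
    if chain is None:
        if not chains:
            raise InputFormatError(f"{path}: no chains")
        chain = next(iter(chains))
    if chain not in chains:
        raise InputFormatError(
            f"{path}: chain {chain!r} not present (has {sorted(chains)})"
        )
    resseqs: list[int] = []
    letters: list[str] = []
    coords: list[np.ndarray] = []
    for res in chains[chain]:
        hetflag, resseq, _icode = res.id
        if hetflag.strip():
            continue  # HETATM
        if "CA" not in res:
            log.warning("chain %s residue %s: no CA atom, skipped", chain, resseq)
            continue
        atom = res["CA"]
        if atom.is_disordered():
            best = max(
                atom.disordered_get_list(),
                key=lambda a: (a.get_occupancy() or 0.0),
            )
            coord = best.get_coord()
        else:
            coord = atom.get_coord()
        resseqs.append(int(resseq))
        letters.append(protein_letters_3to1.get(res.get_resname().strip(), "X"))
        coords.append(np.asarray(coord, dtype=float))
    if not resseqs:
        raise InputFormatError(f"{path}: no CA atoms in chain {chain!r}")
    return CalphaSet(
        chain_id=chain,
        resseqs=tuple(resseqs),
        letters="".join(letters),
        coords=np.vstack(coords),
    )


def map_structure(cs: CalphaSet, ref_seq: str, offset: int | None = None,
                  min_identity: float = 0.95) -> StructureMap:
    """Align the chain's residue string to the ungapped reference by sliding.

    ``offset`` is the number of reference positions preceding the first
    chain residue (may be negative if the chain starts before the
    reference). With ``offset=None`` every overlap is scored and the
    identity-maximizing offset is chosen; it is accepted only if identity
    over the overlap is at least ``min_identity``, otherwise a MappingError
    reports the best offset found so the caller can pass it explicitly. To
    stop a trivially short perfect overlap from beating the true placement,
    auto-detection only considers offsets whose overlap covers at least half
    of the shorter of chain and reference.
    """
    L, n = len(ref_seq), len(cs)
    if L == 0 or n == 0:
        raise MappingError("empty reference or Ca set")

    def overlap_identity(off: int) -> tuple[int, int]:
        match = total = 0
        for j in range(n):
            r = off + j  # 0-based reference index
            if 0 <= r < L:
                total += 1
                if cs.letters[j] == ref_seq[r]:
                    match += 1
        return match, total

    if offset is None:
        min_overlap = max(1, -(-min(n, L) // 2))
        best_off, best_ident = 0, -1.0
        for off in range(-(n - 1), L):
            match, total = overlap_identity(off)
            if total < min_overlap:
                continue
            ident = match / total
            if ident > best_ident:
                best_off, best_ident = off, ident
        if best_ident < min_identity:
            raise MappingError(
                f"auto-mapping failed: best identity {best_ident:.1%} at offset "
                f"{best_off} is below {min_identity:.0%}; pass --offset to force"
            )
        offset = best_off
        identity = best_ident
    else:
        match, total = overlap_identity(offset)
        identity = match / total if total else 0.0

    indices = [UNMAPPED] * L
    for j in range(n):
        r = offset + j
        if 0 <= r < L:
            indices[r] = j
    return StructureMap(indices=tuple(indices), offset=offset, identity=identity)


def distance_matrix(cs: CalphaSet, sm: StructureMap) -> np.ndarray:
    """Symmetric L x L Euclidean Ca distance matrix in A; NaN where unmapped."""
    mapped = [r for r in range(sm.L) if sm.indices[r] != UNMAPPED]
    if len(mapped) < 2:
        raise MappingError(f"only {len(mapped)} mapped position(s); need >= 2")
    coords = cs.coords[[sm.indices[r] for r in mapped]]
    sub = squareform(pdist(coords))
    d = np.full((sm.L, sm.L), np.nan)
    idx = np.array(mapped)
    d[np.ix_(idx, idx)] = sub
    return d


def focus_distances(dm: np.ndarray, f: FocusRegion) -> np.ndarray:
    """Min Ca distance of each residue to the focus region.

    Returns a length-L array: NaN at focus positions (excluded from the
    result) and at unmapped residues. Errors if the whole focus is unmapped.
    """
    L = dm.shape[0]
    if f.end > L:
        raise ValueError(f"focus {f.start}:{f.end} beyond sequence length {L}")
    focus_idx = [p - 1 for p in f.positions()]
    block = dm[:, focus_idx]  # (L, |focus|)
    if not np.any(np.isfinite(block)):
        raise MappingError("entire focus region is unmapped in the structure")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fd = np.nanmin(block, axis=1)
    fd[focus_idx] = np.nan
    return fd


@dataclass(frozen=True)
class ProximityHistogram:
    """Distance distribution of non-focus residues to the focus region."""

    bin_edges: np.ndarray  # A
    counts: np.ndarray


def proximity_histogram(fd: np.ndarray, bin_width: float = 2.0) -> ProximityHistogram:
    """Histogram of finite focus distances in fixed-width A bins from 0."""
    finite = fd[np.isfinite(fd)]
    if finite.size == 0:
        raise ValueError("no finite focus distances")
    top = float(np.ceil(finite.max() / bin_width) * bin_width)
    if top <= 0:
        top = bin_width
    edges = np.arange(0.0, top + bin_width / 2, bin_width)
    counts, _ = np.histogram(finite, bins=edges)
    return ProximityHistogram(bin_edges=edges, counts=counts)


def bundle_chords(fd: np.ndarray, d_lo: float = DEFAULT_D_LO,
                  d_hi: float = DEFAULT_D_HI,
                  min_seq_separation: int = 0,
                  focus: FocusRegion | None = None) -> list[ChordBundle]:
    """Bundle qualifying residues into maximal consecutive-position runs.

    A residue qualifies when d_lo <= focus distance <= d_hi (focus residues
    themselves carry NaN and never qualify). Each run becomes one chord with
    min_distance = its closest member; brightness_rank orders bundles by
    min_distance ascending (0 = darkest = closest). ``min_seq_separation``
    optionally drops residues within that many sequence positions of the
    focus, for contact-map-style separation; by default sequence neighbors
    are kept.
    """
    if d_lo > d_hi:
        raise ValueError(f"d_lo {d_lo} > d_hi {d_hi}")
    qualifying = []
    for i, v in enumerate(fd):
        if not np.isfinite(v) or not (d_lo <= v <= d_hi):
            continue
        pos = i + 1
        if min_seq_separation and focus is not None:
            sep = min(abs(pos - f) for f in focus.positions())
            if sep < min_seq_separation:
                continue
        qualifying.append(pos)
    bundles: list[tuple[int, int, float]] = []
    for pos in qualifying:
        if bundles and pos == bundles[-1][1] + 1:
            start, _, dmin = bundles[-1]
            bundles[-1] = (start, pos, min(dmin, float(fd[pos - 1])))
        else:
            bundles.append((pos, pos, float(fd[pos - 1])))
    order = sorted(range(len(bundles)), key=lambda k: (bundles[k][2], bundles[k][0]))
    ranks = {k: r for r, k in enumerate(order)}
    return [
        ChordBundle(target_start=s, target_end=e, min_distance=dmin,
                    brightness_rank=ranks[k])
        for k, (s, e, dmin) in enumerate(bundles)
    ]
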