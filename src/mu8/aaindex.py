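"""AAindex1 flat-file parsing, standardization, and characteristic-class assignment.

An amino-acid index assigns one number to each of the 20 standard residue
types, quantifying a biophysical property (hydrophobicity, helix propensity,
bulkiness, ...). The AAindex1 database distributes hundreds of such scales as
flat-file records delimited by ``//``; each record's ``I`` section lists the
20 values in two rows of ten, in the canonical residue order

    A R N D C Q E G H I
    L K M F P S T W Y V

Each scale is assigned to one of six characteristic classes following the
Tomii–Kanehisa grouping: alpha/turn propensity, beta propensity,
hydrophobicity, composition, physicochemical, and a catch-all ``other``.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable

from ._errors import InputFormatError

log = logging.getLogger(__name__)

#: Canonical AAindex residue order of the I section (row 1 then row 2).
AAINDEX_RESIDUE_ORDER = tuple("ARNDCQEGHILKMFPSTWYV")

#: The six characteristic classes.
CHAR_CLASSES = (
    "alpha_turn_propensity",
    "beta_propensity",
    "hydrophobicity",
    "composition",
    "physicochemical",
    "other",
)

#: Fixed display order of characteristics (histogram left-to-right ==
#: conservation heat-map top-to-bottom).
CLASS_DISPLAY_ORDER = CHAR_CLASSES

MISSING = math.nan


def is_missing(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)


@dataclass(frozen=True)
class IndexScale:
    """One amino-acid index: a value per standard residue type.

    ``values`` always has exactly 20 keys (one per standard residue letter);
    unmeasured residues carry NaN. An all-missing scale is rejected at parse
    time.
    """

    accession: str
    description: str
    values: dict[str, float]
    char_class: str = "other"

    def __post_init__(self) -> None:
        if set(self.values) != set(AAINDEX_RESIDUE_ORDER):
            raise ValueError(
                f"{self.accession}: values must cover exactly the 20 standard residues"
            )
        if self.char_class not in CHAR_CLASSES:
            raise ValueError(f"{self.accession}: unknown class {self.char_class!r}")
        n_missing = sum(1 for v in self.values.values() if is_missing(v))
        if n_missing > 19:
            raise ValueError(f"{self.accession}: all 20 values missing")

    @property
    def n_missing(self) -> int:
        return sum(1 for v in self.values.values() if is_missing(v))

    def as_vector(self) -> list[float]:
        """Values in canonical AAindex residue order (NaN where missing)."""
        return [self.values[aa] for aa in AAINDEX_RESIDUE_ORDER]


@dataclass(frozen=True)
class ClassMap:
    """accession -> characteristic class."""

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {c for c in self.entries.values() if c not in CHAR_CLASSES}
        if bad:
            raise InputFormatError(
                f"class map contains unknown class labels: {sorted(bad)}; "
                f"allowed: {list(CHAR_CLASSES)}"
            )


def parse_aaindex1(text: str) -> list[IndexScale]:
    """Parse AAindex1 flat-file content into scales.

    ``NA`` tokens become missing values. Every scale starts in class
    ``other``; apply :func:`assign_classes` afterwards. Empty input yields an
    empty list. A record whose I section does not carry exactly 20 tokens
    raises :class:`InputFormatError` naming the accession.
    """
    scales: list[IndexScale] = []
    for record in text.split("//"):
        if not record.strip():
            continue
        accession = ""
        description_lines: list[str] = []
        i_tokens: list[str] = []
        section = ""
        for line in record.splitlines():
            if not line.strip():
                continue
            tag, body = line[:1], line[2:] if len(line) > 2 else ""
            if tag == " ":
                # continuation of the previous section
                if section == "D":
                    description_lines.append(line.strip())
                elif section == "I":
                    i_tokens.extend(line.split())
                continue
            section = tag
            if tag == "H":
                accession = body.strip()
            elif tag == "D":
                description_lines.append(body.strip())
            elif tag == "I":
                # the I header line itself lists residue pairs, not values
                continue
        if not accession and not i_tokens:
            continue
        name = accession or "<no accession>"
        if len(i_tokens) != 20:
            raise InputFormatError(
                f"record {name}: I section has {len(i_tokens)} tokens, expected 20"
            )
        values: dict[str, float] = {}
        for aa, tok in zip(AAINDEX_RESIDUE_ORDER, i_tokens):
            if tok.upper() == "NA":
                values[aa] = MISSING
            else:
                try:
                    values[aa] = float(tok)
                except ValueError as exc:
                    raise InputFormatError(
                        f"record {name}: non-numeric I token {tok!r}"
                    ) from exc
        try:
            scales.append(
                IndexScale(accession=name, description=" ".join(description_lines), values=values)
            )
        except ValueError as exc:
            raise InputFormatError(str(exc)) from exc
    return scales


def format_aaindex1(scales: Iterable[IndexScale]) -> str:
    """Write scales back to AAindex1 flat-file text (round-trips with parse)."""
    out: list[str] = []
    for s in scales:
        out.append(f"H {s.accession}")
        out.append(f"D {s.description}")
        out.append("I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V")
        vec = ["NA" if is_missing(v) else repr(v) for v in s.as_vector()]
        out.append("  " + " ".join(vec[:10]))
        out.append("  " + " ".join(vec[10:]))
        out.append("//")
    return "\n".join(out) + ("\n" if out else "")


def read_classmap(path) -> ClassMap:
    """Read a 2-column TSV ``accession<TAB>class`` (header row required)."""
    entries: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if header.strip() and header.split("\t")[0].strip().lower() != "accession":
            raise InputFormatError(
                f"{path}: expected header 'accession<TAB>class', got {header.strip()!r}"
            )
        for ln, line in enumerate(fh, start=2):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise InputFormatError(f"{path}:{ln}: expected 2 tab-separated fields")
            entries[parts[0].strip()] = parts[1].strip()
    return ClassMap(entries=entries)


def default_classmap() -> ClassMap:
    """The packaged seed class map (best-effort Tomii–Kanehisa grouping)."""
    ref = importlib.resources.files("mu8.data") / "default_classes.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_classmap(path)


def assign_classes(scales: Iterable[IndexScale], cmap: ClassMap) -> list[IndexScale]:
    """Assign each scale its characteristic class; absent accessions fall to ``other``."""
    return [
        replace(s, char_class=cmap.entries.get(s.accession, "other")) for s in scales
    ]


def standardize_scale(scale: IndexScale) -> IndexScale:
    """Center and scale the non-missing values to mean 0, population sd 1.

    The 20 residue types are the complete population a scale describes, so the
    divisor is n, not n-1. Missing values are preserved. A constant scale
    (zero spread) cannot be standardized.
    """
    present = [v for v in scale.values.values() if not is_missing(v)]
    if len(present) < 2:
        raise ValueError(f"{scale.accession}: need >=2 non-missing values")
    mean = sum(present) / len(present)
    var = sum((v - mean) ** 2 for v in present) / len(present)
    if var == 0.0:
        raise ValueError(f"{scale.accession}: constant scale")
    sd = math.sqrt(var)
    new_values = {
        aa: (MISSING if is_missing(v) else (v - mean) / sd)
        for aa, v in scale.values.items()
    }
    return replace(scale, values=new_values)
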