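"""Readers and writers for the formats the accessibility pipeline touches.

All coordinates in this package are 1-based and intervals are inclusive on
both ends (the CT-file convention).  RNA sequences are normalised to the
alphabet {A, C, G, U}: T/t is silently mapped to U; any other character is
an error, because every downstream computation (pairing legality, GC%,
hydrogen-bond weights) needs an unambiguous base.

Supported formats: multi-record FASTA, CT "connect" files, Vienna
dot-bracket strings, Mfold-style ss-count files, delimited siRNA tables
(TSV/CSV, autodetected by extension) and the pipeline's own TSV feature
table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")
LEGAL_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})
EFFICACY_CLASSES = ("VH", "H", "M", "L")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def normalize_rna(seq: str, *, context: str = "sequence") -> str:
    """Uppercase, map T to U and reject anything outside {A,C,G,U}."""
    s = str(seq).strip().upper().replace("T", "U")
    if not s:
        raise ValueError(f"empty {context}")
    bad = set(s) - RNA_ALPHABET
    if bad:
        if "N" in bad:
            raise ValueError(
                f"{context} contains ambiguous base 'N'; only unambiguous "
                "A/C/G/U (or T) are supported"
            )
        raise ValueError(
            f"{context} contains characters outside the RNA alphabet: "
            f"{sorted(bad)}"
        )
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement in RNA space (A<->U, G<->C)."""
    return seq.translate(_COMPLEMENT)[::-1]


def classify_efficacy(percent: float) -> str:
    """Map a silencing-efficacy percentage to the VH/H/M/L class.

    Boundaries: [90,100] -> VH, [70,90) -> H, [50,70) -> M, [0,50) -> L.
    """
    if not 0.0 <= percent <= 100.0:
        raise ValueError(f"efficacy percent {percent} outside [0, 100]")
    if percent >= 90.0:
        return "VH"
    if percent >= 70.0:
        return "H"
    if percent >= 50.0:
        return "M"
    return "L"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MrnaRecord:
    """An mRNA target sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", normalize_rna(self.sequence, context=f"mRNA {self.id!r}")
        )
        if not self.id:
            raise ValueError("mRNA record must have a non-empty id")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SirnaRecord:
    """One siRNA: guide (antisense) strand plus efficacy annotation."""

    id: str
    guide: str
    target_id: str
    efficacy_percent: Optional[float] = None
    efficacy_class: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "guide", normalize_rna(self.guide, context=f"guide of {self.id!r}")
        )
        if not 19 <= len(self.guide) <= 21:
            raise ValueError(
                f"guide length {len(self.guide)} for siRNA {self.id!r} outside 19-21 nt"
            )
        cls = self.efficacy_class
        if self.efficacy_percent is not None:
            derived = classify_efficacy(self.efficacy_percent)
            if cls is None:
                object.__setattr__(self, "efficacy_class", derived)
            elif cls != derived:
                raise ValueError(
                    f"siRNA {self.id!r}: efficacy class {cls} inconsistent with "
                    f"{self.efficacy_percent}% (expected {derived})"
                )
        elif cls is not None:
            if cls not in EFFICACY_CLASSES:
                raise ValueError(f"unknown efficacy token {cls!r} for siRNA {self.id!r}")
        else:
            raise ValueError(f"siRNA {self.id!r} has neither efficacy percent nor class")


def _validate_pairs(sequence: str, pairs: Sequence[int]) -> None:
    n = len(sequence)
    if len(pairs) != n + 1 or pairs[0] != 0:
        raise ValueError(
            f"pair table must have length {n + 1} with a zero sentinel at index 0"
        )
    for i in range(1, n + 1):
        j = pairs[i]
        if j == 0:
            continue
        if not 1 <= j <= n:
            raise ValueError(f"position {i} pairs with out-of-range position {j}")
        if j == i:
            raise ValueError(f"position {i} pairs with itself")
        if pairs[j] != i:
            raise ValueError(
                f"involution violated: position {i} pairs {j} but position {j} "
                f"pairs {pairs[j]}"
            )
        if j > i:
            duo = sequence[i - 1] + sequence[j - 1]
            if duo not in LEGAL_PAIRS:
                raise ValueError(
                    f"illegal base pair {sequence[i-1]}-{sequence[j-1]} at "
                    f"positions {i}-{j}"
                )
    # nestedness: a closing position must match the innermost open pair
    stack: List[int] = []
    for i in range(1, n + 1):
        j = pairs[i]
        if j > i:
            stack.append(j)
        elif j and j < i:
            if not stack or stack[-1] != i:
                raise ValueError(
                    f"pseudoknot: pair {j}-{i} crosses an enclosing pair"
                )
            stack.pop()
    # hairpin-closing pairs must enclose at least 3 unpaired nucleotides
    for i in range(1, n + 1):
        j = pairs[i]
        if j > i and all(pairs[k] == 0 for k in range(i + 1, j)):
            if j - i - 1 < 3:
                raise ValueError(
                    f"hairpin loop closed by {i}-{j} spans {j - i - 1} < 3 nt"
                )


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested secondary structure: sequence plus 1-based pair table.

    ``pairs[i] == j`` means position i pairs position j; 0 means unpaired.
    ``pairs[0]`` is a zero sentinel so indices are 1-based.  ``energy`` is
    the structure's score (kcal/mol for external structures; negated
    hydrogen-bond weight for the internal engine) — more negative is more
    stable.
    """

    sequence: str
    pairs: Tuple[int, ...]
    energy: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", normalize_rna(self.sequence, context="structure sequence")
        )
        object.__setattr__(self, "pairs", tuple(int(p) for p in self.pairs))
        _validate_pairs(self.sequence, self.pairs)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def is_unpaired(self, i: int) -> bool:
        return self.pairs[i] == 0

    def dotbracket(self) -> str:
        out = []
        for i in range(1, self.length + 1):
            j = self.pairs[i]
            out.append("." if j == 0 else ("(" if j > i else ")"))
        return "".join(out)


@dataclass(frozen=True)
class SsCountVector:
    """Per-position single-stranded counts over a structure ensemble.

    ``counts[i]`` (1-based, with a zero sentinel at index 0) is the number
    of ensemble structures in which position i is unpaired.
    """

    counts: Tuple[int, ...]
    n_structures: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        if self.n_structures < 1:
            raise ValueError("n_structures must be positive")
        if not self.counts or self.counts[0] != 0:
            raise ValueError("counts must carry a zero sentinel at index 0")
        for i, c in enumerate(self.counts[1:], start=1):
            if not 0 <= c <= self.n_structures:
                raise ValueError(
                    f"ss-count {c} at position {i} outside [0, {self.n_structures}]"
                )

    @property
    def length(self) -> int:
        return len(self.counts) - 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> List[MrnaRecord]:
    """Read a (multi-record) FASTA file into normalised mRNA records."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty sequence for FASTA record {rec.id!r} in {path}")
        records.append(MrnaRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[MrnaRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for k in range(0, rec.length, 60):
                fh.write(rec.sequence[k : k + 60] + "\n")


# ---------------------------------------------------------------------------
# CT connect format
# ---------------------------------------------------------------------------

_DG_RE = re.compile(r"dG\s*=\s*(-?\d+(?:\.\d+)?)", re.IGNORECASE)


def _maybe_real(token: str) -> Optional[float]:
    try:
        return float(token)
    except ValueError:
        return None


def read_ct(path) -> SecondaryStructure:
    """Read a CT "connect" file (header line, then one row per nucleotide).

    The header carries the length and, optionally, an energy as either a
    ``dG = x`` token or a bare real.  Trailing columns beyond the canonical
    six are ignored.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty CT file {path}")
    header = lines[0]
    tokens = header.split()
    try:
        length = int(tokens[0])
    except ValueError as exc:
        raise ValueError(f"CT header of {path} does not start with a length") from exc
    m = _DG_RE.search(header)
    if m:
        energy: Optional[float] = float(m.group(1))
    else:
        energy = _maybe_real(tokens[1]) if len(tokens) > 1 else None
    rows = lines[1 : 1 + length]
    if len(rows) != length:
        raise ValueError(
            f"CT file {path} declares {length} rows but contains {len(rows)}"
        )
    seq_chars: List[str] = []
    pairs = [0] * (length + 1)
    for expect, row in enumerate(rows, start=1):
        cols = row.split()
        if len(cols) < 6:
            raise ValueError(f"CT row {expect} of {path} has fewer than 6 columns")
        i = int(cols[0])
        if i != expect:
            raise ValueError(f"CT row {expect} of {path} is numbered {i}")
        j = int(cols[4])
        if not 0 <= j <= length:
            raise ValueError(f"CT row {i} of {path} pairs out-of-range position {j}")
        seq_chars.append(cols[1])
        pairs[i] = j
    for i in range(1, length + 1):
        j = pairs[i]
        if j and pairs[j] != i:
            raise ValueError(
                f"CT file {path}: involution violated between rows {i} and {j} "
                f"(row {i} pairs {j}, row {j} pairs {pairs[j]})"
            )
    sequence = normalize_rna("".join(seq_chars), context=f"CT file {path}")
    return SecondaryStructure(sequence=sequence, pairs=tuple(pairs), energy=energy)


def write_ct(structure: SecondaryStructure, path, title: str = "structure") -> None:
    n = structure.length
    with open(path, "w") as fh:
        if structure.energy is not None:
            fh.write(f"{n} dG = {structure.energy:.2f} {title}\n")
        else:
            fh.write(f"{n} {title}\n")
        for i in range(1, n + 1):
            fh.write(
                f"{i} {structure.sequence[i-1]} {i-1} "
                f"{i+1 if i < n else 0} {structure.pairs[i]} {i}\n"
            )


# ---------------------------------------------------------------------------
# Vienna dot-bracket
# ---------------------------------------------------------------------------


def read_dotbracket(seq: str, db: str, energy: Optional[float] = None) -> SecondaryStructure:
    """Build a structure from a sequence and a dot-bracket string."""
    sequence = normalize_rna(seq, context="dot-bracket sequence")
    if len(sequence) != len(db):
        raise ValueError(
            f"sequence length {len(sequence)} != bracket length {len(db)}"
        )
    bad = set(db) - set(".()")
    if bad:
        raise ValueError(f"dot-bracket string contains {sorted(bad)}")
    pairs = [0] * (len(sequence) + 1)
    stack: List[int] = []
    for i, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairs[j] = i
            pairs[i] = j
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return SecondaryStructure(sequence=sequence, pairs=tuple(pairs), energy=energy)


# ---------------------------------------------------------------------------
# Mfold ss-count dialect
# ---------------------------------------------------------------------------


def read_ss_count(path) -> SsCountVector:
    """Read an ss-count file: first line N, then "position count [base]"."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty ss-count file {path}")
    try:
        n_structures = int(lines[0].split()[0])
    except ValueError as exc:
        raise ValueError(f"ss-count file {path} must start with the ensemble size") from exc
    counts = [0]
    for expect, ln in enumerate(lines[1:], start=1):
        cols = ln.split()
        pos = int(cols[0])
        if pos != expect:
            raise ValueError(f"ss-count file {path}: missing position {expect}")
        count = int(cols[1])
        if not 0 <= count <= n_structures:
            raise ValueError(
                f"ss-count file {path}: count {count} at position {pos} exceeds "
                f"ensemble size {n_structures}"
            )
        counts.append(count)
    if len(counts) == 1:
        raise ValueError(f"ss-count file {path} has no positions")
    return SsCountVector(counts=tuple(counts), n_structures=n_structures)


def write_ss_count(ss: SsCountVector, path, sequence: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"{ss.n_structures}\n")
        for i in range(1, ss.length + 1):
            if sequence is not None:
                fh.write(f"{i} {ss.counts[i]} {sequence[i-1]}\n")
            else:
                fh.write(f"{i} {ss.counts[i]}\n")


# ---------------------------------------------------------------------------
# siRNA tables
# ---------------------------------------------------------------------------


def read_sirna_table(path) -> List[SirnaRecord]:
    """Read a delimited siRNA table with columns id, guide, target_id, efficacy.

    The delimiter is autodetected from the extension (.csv -> comma,
    anything else -> tab).  The efficacy column may hold either a percent
    in [0,100] or one of the tokens VH/H/M/L.
    """
    import pandas as pd

    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"id", "guide", "target_id", "efficacy"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"siRNA table {path} lacks columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        token = str(row["efficacy"]).strip()
        percent = _maybe_real(token)
        if percent is not None:
            rec = SirnaRecord(
                id=str(row["id"]).strip(),
                guide=str(row["guide"]),
                target_id=str(row["target_id"]).strip(),
                efficacy_percent=percent,
            )
        else:
            cls = token.upper()
            if cls not in EFFICACY_CLASSES:
                raise ValueError(
                    f"unknown efficacy token {token!r} for siRNA {row['id']!r}"
                )
            rec = SirnaRecord(
                id=str(row["id"]).strip(),
                guide=str(row["guide"]),
                target_id=str(row["target_id"]).strip(),
                efficacy_class=cls,
            )
        records.append(rec)
    return records


def write_sirna_table(records: Iterable[SirnaRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tguide\ttarget_id\tefficacy\n")
        for rec in records:
            if rec.efficacy_percent is not None:
                eff = f"{rec.efficacy_percent:.1f}"
            else:
                eff = rec.efficacy_class or ""
            fh.write(f"{rec.id}\t{rec.guide}\t{rec.target_id}\t{eff}\n")


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

#: Fixed column order of the per-siRNA feature table.  The eight element
#: columns follow the analysis tables' order.
FEATURE_COLUMNS = (
    "sirna_id",
    "efficacy_code",
    "loop5",
    "loop3",
    "int_loop",
    "mb_loop",
    "h_loop",
    "b_loop",
    "one_bb",
    "stem",
    "n_unpaired",
    "runs",
    "max_run",
    "hb_index",
    "dg_overall",
    "dg_duplex",
    "dg_break_target",
    "dg_oligo_self",
    "gc_percent",
)

_INT_FEATURES = {
    "efficacy_code",
    "loop5",
    "loop3",
    "int_loop",
    "mb_loop",
    "h_loop",
    "b_loop",
    "one_bb",
    "stem",
    "n_unpaired",
    "max_run",
}

_REAL_FEATURES = {
    "hb_index",
    "dg_overall",
    "dg_duplex",
    "dg_break_target",
    "dg_oligo_self",
    "gc_percent",
}


def _format_feature(name: str, value) -> str:
    if name == "runs":
        return ",".join(str(int(r)) for r in value)
    if name in _REAL_FEATURES:
        return f"{float(value):.4f}"
    if name in _INT_FEATURES:
        return str(int(value))
    return str(value)


def write_feature_table(rows: Sequence, path) -> None:
    """Write feature vectors as TSV with a fixed column order.

    Reals are formatted to 4 decimals; the ``runs`` list is comma-joined.
    An empty row list produces a header-only file.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(FEATURE_COLUMNS) + "\n")
        for row in rows:
            fh.write(
                "\t".join(_format_feature(c, getattr(row, c)) for c in FEATURE_COLUMNS)
                + "\n"
            )


def read_feature_table(path) -> list:
    """Inverse of :func:`write_feature_table` (to formatting precision)."""
    from .site_features import SiteFeatureVector

    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"empty feature table {path}")
    header = lines[0].split("\t")
    if tuple(header) != FEATURE_COLUMNS:
        raise ValueError(f"feature table {path} has unexpected columns")
    rows = []
    for ln in lines[1:]:
        vals = ln.split("\t")
        kw = {}
        for name, raw in zip(FEATURE_COLUMNS, vals):
            if name == "runs":
                kw[name] = tuple(int(x) for x in raw.split(",") if x)
            elif name in _INT_FEATURES:
                kw[name] = int(raw)
            elif name in _REAL_FEATURES:
                kw[name] = float(raw)
            else:
                kw[name] = raw
        rows.append(SiteFeatureVector(**kw))
    return rows
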