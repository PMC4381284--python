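"""Loop decomposition: classify every nucleotide of a nested structure.

Each position of a secondary structure receives exactly one of eight
element labels (a partition of the sequence):

* ``STEM`` — paired positions;
* ``H_LOOP`` — hairpin loop (loop with no interior branch);
* ``INT_LOOP`` — internal loop (one branch, unpaired on both sides);
* ``B_LOOP`` — bulge loop (one branch, >= 2 unpaired on one side only);
* ``ONE_BB`` — one-base bulge (one branch, exactly 1 unpaired, one side);
* ``MB_LOOP`` — multibranch loop (>= 2 interior branches);
* ``LOOP_5P`` / ``LOOP_3P`` — exterior unpaired positions (see below).

An unpaired base belongs to the loop closed by its nearest enclosing base
pair (standard loop decomposition), which makes the labelling unique.
Exterior positions upstream of the first helix are ``LOOP_5P`` and
positions downstream of the last helix are ``LOOP_3P``; an exterior
segment between two helices is split at its midpoint — the 5' half dangles
3' of the preceding helix (``LOOP_3P``), the 3' half is ``LOOP_5P``, and
an odd middle position goes to ``LOOP_5P``.  A structure with no pairs is
all ``LOOP_5P``.  These exterior conventions are a documented
interpretation; the literature does not fix them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

from .structure_io import SecondaryStructure

STEM = "STEM"
H_LOOP = "H_LOOP"
INT_LOOP = "INT_LOOP"
B_LOOP = "B_LOOP"
ONE_BB = "ONE_BB"
MB_LOOP = "MB_LOOP"
LOOP_5P = "LOOP_5P"
LOOP_3P = "LOOP_3P"

#: All labels, in the column order used by the result tables.
ELEMENT_LABELS = (LOOP_5P, LOOP_3P, INT_LOOP, MB_LOOP, H_LOOP, B_LOOP, ONE_BB, STEM)

#: Feature-table column name for each label.
ELEMENT_COLUMNS: Dict[str, str] = {
    LOOP_5P: "loop5",
    LOOP_3P: "loop3",
    INT_LOOP: "int_loop",
    MB_LOOP: "mb_loop",
    H_LOOP: "h_loop",
    B_LOOP: "b_loop",
    ONE_BB: "one_bb",
    STEM: "stem",
}

_LABEL_CHARS = {
    STEM: "S",
    H_LOOP: "H",
    INT_LOOP: "I",
    B_LOOP: "B",
    ONE_BB: "b",
    MB_LOOP: "M",
    LOOP_5P: "5",
    LOOP_3P: "3",
}


@dataclass(frozen=True)
class ElementAnnotation:
    """Per-position element labels (1-based; index 0 is a sentinel).

    ``instance_ids[i]`` identifies the element instance position i belongs
    to: one id per loop, per exterior segment and per helix (maximal stack
    of pairs), so "number of element instances touched" is countable.
    """

    labels: Tuple[str, ...]
    instance_ids: Tuple[int, ...]
    structure: SecondaryStructure

    def __post_init__(self) -> None:
        n = self.structure.length
        if len(self.labels) != n + 1 or len(self.instance_ids) != n + 1:
            raise ValueError("annotation length must equal sequence length + 1")

    def label_string(self) -> str:
        """Compact one-character-per-position rendering (debugging aid)."""
        return "".join(_LABEL_CHARS[l] for l in self.labels[1:])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tlabel\n")
            for i in range(1, self.structure.length + 1):
                fh.write(f"{i}\t{self.labels[i]}\n")


def _children_of(pairs: Tuple[int, ...], n: int):
    """Tree of pairs: returns (top_level, children) where children maps a
    closing pair (a, b) to its directly nested pairs, left to right."""
    top: List[Tuple[int, int]] = []
    children: Dict[Tuple[int, int], List[Tuple[int, int]]] = {}
    stack: List[Tuple[int, int]] = []
    i = 1
    while i <= n:
        j = pairs[i]
        if j > i:
            node = (i, j)
            children[node] = []
            if stack:
                children[stack[-1]].append(node)
            else:
                top.append(node)
            stack.append(node)
        elif j != 0 and j < i:
            stack.pop()
        i += 1
    return top, children


def annotate(structure: SecondaryStructure) -> ElementAnnotation:
    """Partition every position of ``structure`` into the 8 element classes."""
    n = structure.length
    pairs = structure.pairs
    labels: List[str] = [""] * (n + 1)
    inst: List[int] = [0] * (n + 1)
    next_id = 1

    # stems, one instance id per helix (maximal stack of pairs)
    for i in range(1, n + 1):
        if pairs[i] != 0:
            labels[i] = STEM
    helix_id: Dict[Tuple[int, int], int] = {}
    for i in range(1, n + 1):
        j = pairs[i]
        if j > i:
            if pairs[i - 1] == j + 1 and (i - 1, j + 1) in helix_id:
                hid = helix_id[(i - 1, j + 1)]
            else:
                hid = next_id
                next_id += 1
            helix_id[(i, j)] = hid
            inst[i] = inst[j] = hid

    top, children = _children_of(pairs, n)

    def fill(positions: List[int], label: str, loop_id: int) -> None:
        for p in positions:
            labels[p] = label
            inst[p] = loop_id

    # interior loops, one instance per closing pair
    for (a, b), kids in children.items():
        gaps: List[List[int]] = []
        cursor = a + 1
        for (c, d) in kids:
            gaps.append([p for p in range(cursor, c)])
            cursor = d + 1
        gaps.append([p for p in range(cursor, b)])
        unpaired = [p for gap in gaps for p in gap]
        if not unpaired:
            continue
        loop_id = next_id
        next_id += 1
        if len(kids) == 0:
            fill(unpaired, H_LOOP, loop_id)
        elif len(kids) == 1:
            left, right = len(gaps[0]), len(gaps[1])
            if left > 0 and right > 0:
                fill(unpaired, INT_LOOP, loop_id)
            elif left + right == 1:
                fill(unpaired, ONE_BB, loop_id)
            else:
                fill(unpaired, B_LOOP, loop_id)
        else:
            fill(unpaired, MB_LOOP, loop_id)

    # exterior positions
    if not top:
        seg = list(range(1, n + 1))
        if seg:
            fill(seg, LOOP_5P, next_id)
            next_id += 1
    else:
        first_a = top[0][0]
        last_b = top[-1][1]
        head = list(range(1, first_a))
        if head:
            fill(head, LOOP_5P, next_id)
            next_id += 1
        for (a1, b1), (a2, b2) in zip(top, top[1:]):
            seg = list(range(b1 + 1, a2))
            if not seg:
                continue
            m = len(seg)
            half3 = seg[: m // 2]  # dangles 3' of the preceding helix
            half5 = seg[m // 2 :]  # leads 5' into the next helix
            if half3:
                fill(half3, LOOP_3P, next_id)
                next_id += 1
            if half5:
                fill(half5, LOOP_5P, next_id)
                next_id += 1
        tail = list(range(last_b + 1, n + 1))
        if tail:
            fill(tail, LOOP_3P, next_id)
            next_id += 1

    return ElementAnnotation(
        labels=tuple(labels), instance_ids=tuple(inst), structure=structure
    )


def element_counts_in_site(
    annotation: ElementAnnotation, site: Tuple[int, int], unit: str = "bases"
) -> Dict[str, int]:
    """Per-element tallies within a 1-based inclusive window.

    ``unit="bases"`` (default) counts targeted bases per element class,
    summing to the window length; ``unit="instances"`` counts distinct
    element instances touched by the window.
    """
    start, end = site
    n = annotation.structure.length
    if not (1 <= start <= end <= n):
        raise ValueError(f"site {site} outside 1..{n}")
    counts = {label: 0 for label in ELEMENT_LABELS}
    if unit == "bases":
        for i in range(start, end + 1):
            counts[annotation.labels[i]] += 1
    elif unit == "instances":
        seen = set()
        for i in range(start, end + 1):
            key = (annotation.labels[i], annotation.instance_ids[i])
            if key not in seen:
                seen.add(key)
                counts[annotation.labels[i]] += 1
    else:
        raise ValueError(f"unknown counting unit {unit!r}")
    return counts
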