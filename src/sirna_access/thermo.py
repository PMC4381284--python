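"""Thermodynamic and composition features of siRNA-target binding.

Implements the three binding-affinity terms used throughout the analysis,
all in kcal/mol with "more negative = more stable/tighter":

* ``dg_duplex`` — hybridization free energy of the guide:target duplex
  from unstructured strands, via a nearest-neighbor sum over stacked pairs
  (packaged Watson-Crick parameter table, 37 C) plus duplex initiation and
  per-terminal AU penalties;
* ``dg_break_target`` — (negated) cost of opening every target-site base
  pair so the site is completely single-stranded: optimal-fold score minus
  site-constrained-fold score.  Always <= 0; more negative means a less
  accessible site;
* ``dg_oligo_self`` — (negated) stability of the guide's own optimal
  self-structure, <= 0;
* ``dg_overall`` — net binding energy: duplex minus break-target minus
  self terms, hence always >= dg_duplex.

The break/self terms use the internal engine's hydrogen-bond scores unless
external fold energies are supplied, so absolute values are engine-scale;
the identities and orderings between the terms hold on either scale.

GC content is binned into the main ranges <25%, 25-55% (closed) and >55%,
with subgroups [25,35), [35,45), [45,55) and [55,65).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

from .fold_engine import FoldParams, fold_constrained, fold_optimal
from .structure_io import normalize_rna, reverse_complement

_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class NNParameterSet:
    """Nearest-neighbor duplex parameters.

    ``stack_energies`` maps a stack key "XY/WZ" (top strand 5'XY3' over
    bottom strand 3'WZ5') to kcal/mol.  All 16 Watson-Crick stacks must be
    present and consistent under rotational equivalence.
    """

    stack_energies: Mapping[str, float]
    init_penalty: float
    terminal_au_penalty: float
    source_tag: str = "unspecified"

    def __post_init__(self) -> None:
        keys = [
            f"{x}{y}/{_WC[x]}{_WC[y]}" for x in "ACGU" for y in "ACGU"
        ]
        for key in keys:
            if key not in self.stack_energies:
                raise ValueError(f"nearest-neighbor set lacks stack {key}")
        for x in "ACGU":
            for y in "ACGU":
                key = f"{x}{y}/{_WC[x]}{_WC[y]}"
                rot = f"{_WC[y]}{_WC[x]}/{y}{x}"
                if abs(self.stack_energies[key] - self.stack_energies[rot]) > 1e-9:
                    raise ValueError(
                        f"stacks {key} and {rot} must agree (rotational equivalence)"
                    )

    def stack(self, top_dinucleotide: str) -> float:
        x, y = top_dinucleotide[0], top_dinucleotide[1]
        return self.stack_energies[f"{x}{y}/{_WC[x]}{_WC[y]}"]


def load_nn_params(path=None) -> NNParameterSet:
    """Load a nearest-neighbor parameter file (default: packaged table).

    Format: tab-separated rows "XY/WZ<tab>energy" plus named rows
    ``init``, ``terminal_au`` and optional ``source``; '#' comments.
    """
    if path is None:
        ref = resources.files("sirna_access").joinpath("data/nn_rna_wc37.tsv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    stacks: Dict[str, float] = {}
    init = None
    term = None
    source = "unspecified"
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        key, value = ln.split("\t")
        if key == "init":
            init = float(value)
        elif key == "terminal_au":
            term = float(value)
        elif key == "source":
            source = value
        else:
            stacks[key] = float(value)
    if init is None or term is None:
        raise ValueError("parameter file must define 'init' and 'terminal_au' rows")
    return NNParameterSet(
        stack_energies=stacks,
        init_penalty=init,
        terminal_au_penalty=term,
        source_tag=source,
    )


_DEFAULT_PARAMS: Optional[NNParameterSet] = None


def default_nn_params() -> NNParameterSet:
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        _DEFAULT_PARAMS = load_nn_params()
    return _DEFAULT_PARAMS


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GcBinning:
    """Main GC bins <25% / [25,55] / >55% plus half-open subgroups."""

    main_low: float = 25.0
    main_high: float = 55.0
    subgroups: Tuple[Tuple[float, float], ...] = (
        (25.0, 35.0),
        (35.0, 45.0),
        (45.0, 55.0),
        (55.0, 65.0),
    )

    def main_labels(self) -> Tuple[str, str, str]:
        return (
            f"<{self.main_low:g}%",
            f"{self.main_low:g}-{self.main_high:g}%",
            f">{self.main_high:g}%",
        )

    def subgroup_label(self, lo: float, hi: float) -> str:
        return f"{lo:g}-{hi - 1:g}%"


DEFAULT_GC_BINNING = GcBinning()


def gc_percent(seq: str) -> float:
    """100 * (#G + #C) / length."""
    s = normalize_rna(seq, context="GC input")
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def gc_bin(
    gc: float, binning: GcBinning = DEFAULT_GC_BINNING
) -> Tuple[str, Optional[str]]:
    """Assign a GC percentage to its main bin and (if any) subgroup."""
    if not 0.0 <= gc <= 100.0:
        raise ValueError(f"GC percent {gc} outside [0, 100]")
    lo_lbl, mid_lbl, hi_lbl = binning.main_labels()
    if gc < binning.main_low:
        main = lo_lbl
    elif gc <= binning.main_high:
        main = mid_lbl
    else:
        main = hi_lbl
    sub = None
    for s_lo, s_hi in binning.subgroups:
        if s_lo <= gc < s_hi:
            sub = binning.subgroup_label(s_lo, s_hi)
            break
    return main, sub


# ---------------------------------------------------------------------------
# Free-energy terms
# ---------------------------------------------------------------------------


def dg_duplex(
    guide: str, target_site_seq: str, params: Optional[NNParameterSet] = None
) -> float:
    """Nearest-neighbor hybridization energy of a fully complementary duplex.

    ``target_site_seq`` must be the exact reverse complement of ``guide``
    (wobble pairs are not allowed in the duplex).  The sum runs over the
    len-1 stacks of the duplex plus initiation and terminal-AU penalties.
    """
    params = params or default_nn_params()
    g = normalize_rna(guide, context="guide")
    t = normalize_rna(target_site_seq, context="target site")
    if len(t) < 2:
        raise ValueError("duplex must be at least 2 bp")
    if t != reverse_complement(g):
        raise ValueError("guide and target site are not exact reverse complements")
    total = params.init_penalty
    for i in range(len(t) - 1):
        total += params.stack(t[i : i + 2])
    if t[0] in "AU":
        total += params.terminal_au_penalty
    if t[-1] in "AU":
        total += params.terminal_au_penalty
    return total


def dg_break_target(
    seq: str,
    site: Tuple[int, int],
    fold_params: Optional[FoldParams] = None,
    external_energies: Optional[Tuple[float, float]] = None,
) -> float:
    """Negated cost of opening the target site: optimal minus site-open score.

    ``external_energies`` = (unconstrained, site-constrained) fold energies
    from an external folder take precedence over the internal engine.
    Returns a value <= 0; 0 when the site is already unpaired in the
    optimal fold.
    """
    if external_energies is not None:
        unconstrained, constrained = external_energies
    else:
        unconstrained = fold_optimal(seq, fold_params).energy
        constrained = fold_constrained(seq, site, fold_params).energy
    value = unconstrained - constrained
    if value > 1e-9:
        raise ValueError(
            "constrained fold scored better than the unconstrained optimum; "
            "inconsistent energies"
        )
    return min(value, 0.0)


def dg_oligo_self(guide: str, fold_params: Optional[FoldParams] = None) -> float:
    """Negated stability of the guide's optimal self-fold (<= 0)."""
    return fold_optimal(guide, fold_params).energy


def dg_overall(dg_duplex_val: float, dg_break_target_val: float, dg_self_val: float) -> float:
    """Net binding energy once target opening and self-structure are paid.

    ``dg_overall = dg_duplex - dg_break_target - dg_oligo_self`` with the
    break and self terms <= 0 by convention, hence the result is never
    below ``dg_duplex``.
    """
    if dg_break_target_val > 0 or dg_self_val > 0:
        raise ValueError(
            "break-target and oligo-self terms must be <= 0 (negated stabilities)"
        )
    return dg_duplex_val - dg_break_target_val - dg_self_val
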