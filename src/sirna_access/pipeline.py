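"""End-to-end orchestration: inputs -> feature table -> result bundle.

The result bundle mirrors the analysis artifacts of a two-group siRNA
accessibility study:

* ``features.tsv`` — one predictor row per siRNA;
* ``unpaired_by_element.tsv`` — siRNA counts by number of targeted bases
  per element class and efficacy group;
* ``logistic_elements.tsv`` — univariable and multivariable odds ratios
  with robust 95% CIs for the eight element predictors;
* ``logistic_other.tsv`` — univariable ORs for the remaining predictors
  (unpaired bases, longest run, H-b, free-energy terms, GC%);
* ``unpaired_hist.tsv`` / ``runs_hist.tsv`` — per-group distributions of
  unpaired bases and of consecutive-unpaired run lengths;
* ``group_comparisons.tsv`` — mean±S.D. group contrasts of the continuous
  predictors with the test used and its p-value;
* ``gc_bins.tsv`` / ``gc_tests.tsv`` — GC-content bin memberships with
  Fisher, chi-square and exact-binomial results;
* ``run_log.jsonl`` — machine-readable log (versions, seed, parameter
  digest, one record per siRNA).

Every statistic is a pure function of the feature table, so the bundle is
recomputable from ``features.tsv`` alone; with fixed inputs and seed the
bundle is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .fold_engine import FoldParams, StructureEnsemble, representative_ensemble, ss_count
from .loop_annotation import ELEMENT_COLUMNS, ELEMENT_LABELS
from .site_features import SiteFeatureVector, build_feature_vector
from .stats import (
    RankDeficiencyError,
    SeparationError,
    chi_square_rxc,
    fisher_exact_2x2,
    logistic_multivariable,
    logistic_univariable,
    one_sample_proportion,
    two_group_compare,
)
from .structure_io import (
    FEATURE_COLUMNS,
    MrnaRecord,
    SirnaRecord,
    read_ct,
    read_fasta,
    read_sirna_table,
    read_ss_count,
    write_feature_table,
)
from . import thermo

logger = logging.getLogger(__name__)

ELEMENT_FEATURES = tuple(ELEMENT_COLUMNS[l] for l in ELEMENT_LABELS)
OTHER_PREDICTORS = (
    "n_unpaired",
    "max_run",
    "hb_index",
    "dg_overall",
    "dg_duplex",
    "dg_break_target",
    "gc_percent",
)
COMPARED_PREDICTORS = (
    "hb_index",
    "dg_overall",
    "dg_duplex",
    "dg_break_target",
    "dg_oligo_self",
    "gc_percent",
)


@dataclass
class RunConfig:
    """Configuration of an end-to-end run (flat key=value file or CLI)."""

    fasta: Optional[str] = None
    sirna_table: Optional[str] = None
    structures_dir: Optional[str] = None
    sscount_dir: Optional[str] = None
    outdir: str = "results"
    seed: int = 0
    hb_cutpoint: float = 25.0
    robust: bool = True
    normality_rule: str = "shapiro"
    min_hairpin: int = 3
    ensemble_windows: int = 4
    nn_params_file: Optional[str] = None

    def __post_init__(self) -> None:
        if self.hb_cutpoint <= 0:
            raise ValueError("H-b cutpoint must be positive")

    def fold_params(self) -> FoldParams:
        return FoldParams(min_hairpin=self.min_hairpin)

    def validate_paths(self) -> None:
        for name in ("fasta", "sirna_table", "structures_dir", "sscount_dir"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name} path does not exist: {value}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs = {}
        for ln in Path(path).read_text().splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            key, _, value = ln.partition("=")
            key = key.strip()
            value = value.strip()
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"unknown config key {key!r}")
            if key in ("seed", "min_hairpin", "ensemble_windows"):
                kwargs[key] = int(value)
            elif key == "hb_cutpoint":
                kwargs[key] = float(value)
            elif key == "robust":
                kwargs[key] = value.lower() in ("1", "true", "yes")
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def digest(self) -> str:
        """Hash of the analysis parameters (the output location is excluded)."""
        payload = json.dumps(
            {k: v for k, v in asdict(self).items() if k != "outdir"},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Feature computation
# ---------------------------------------------------------------------------


def _external_ensemble(structures_dir: Path, mrna: MrnaRecord) -> Optional[StructureEnsemble]:
    ct_files = sorted(structures_dir.glob(f"{mrna.id}*.ct"))
    if not ct_files:
        return None
    structures = []
    for f in ct_files:
        s = read_ct(f)
        if s.sequence != mrna.sequence:
            raise ValueError(
                f"structure file {f} disagrees with the sequence of mRNA {mrna.id}"
            )
        structures.append(s)
    structures.sort(key=lambda s: (s.energy if s.energy is not None else 0.0, s.pairs))
    return StructureEnsemble(
        sequence=mrna.sequence,
        structures=tuple(structures),
        scores=tuple(s.energy if s.energy is not None else 0.0 for s in structures),
    )


def compute_features(
    mrnas: List[MrnaRecord],
    sirnas: List[SirnaRecord],
    config: RunConfig,
) -> Tuple[List[SiteFeatureVector], List[dict]]:
    """Feature rows for every VH/L siRNA, plus structured log records.

    External CT structures (``structures_dir``) take precedence over the
    internal engine; external ss-count files (``sscount_dir``) take
    precedence over ensemble-derived counts.  H/M siRNAs are skipped with
    a log record — the analysis contrasts the extreme groups only.
    """
    by_id = {m.id: m for m in mrnas}
    fold_params = config.fold_params()
    nn_params = (
        thermo.load_nn_params(config.nn_params_file)
        if config.nn_params_file
        else thermo.default_nn_params()
    )
    structures_dir = Path(config.structures_dir) if config.structures_dir else None
    sscount_dir = Path(config.sscount_dir) if config.sscount_dir else None
    ensembles: Dict[str, StructureEnsemble] = {}
    features: List[SiteFeatureVector] = []
    log_records: List[dict] = []
    for sirna in sirnas:
        if sirna.efficacy_class not in ("VH", "L"):
            log_records.append(
                {
                    "event": "skip",
                    "sirna": sirna.id,
                    "reason": f"class {sirna.efficacy_class} outside VH/L",
                }
            )
            continue
        if sirna.target_id not in by_id:
            raise ValueError(
                f"stage features: siRNA {sirna.id!r} targets unknown mRNA "
                f"{sirna.target_id!r}"
            )
        mrna = by_id[sirna.target_id]
        if mrna.id not in ensembles:
            external = _external_ensemble(structures_dir, mrna) if structures_dir else None
            if external is not None:
                ensembles[mrna.id] = external
            else:
                ensembles[mrna.id] = representative_ensemble(
                    mrna.sequence, fold_params, config.ensemble_windows
                )
        ensemble = ensembles[mrna.id]
        ss = None
        if sscount_dir is not None:
            ss_file = sscount_dir / f"{mrna.id}.sscount"
            if ss_file.exists():
                ss = read_ss_count(ss_file)
                if ss.length != mrna.length:
                    raise ValueError(
                        f"stage features: ss-count file {ss_file} length "
                        f"{ss.length} != mRNA length {mrna.length}"
                    )
        if ss is None and structures_dir is None:
            logger.info(
                "mRNA %s: H-b denominator is the internal surrogate ensemble "
                "(%d structures), not a folding-server ss-count",
                mrna.id,
                ensemble.size,
            )
        try:
            fv = build_feature_vector(
                sirna, mrna, ensemble, fold_params=fold_params,
                nn_params=nn_params, ss=ss,
            )
        except ValueError as exc:
            raise ValueError(f"stage features: siRNA {sirna.id!r}: {exc}") from exc
        features.append(fv)
        log_records.append(
            {
                "event": "sirna",
                "sirna": sirna.id,
                "mrna": mrna.id,
                "site_start": _site_start(fv, sirna, mrna),
                "elements": {
                    c: getattr(fv, c) for c in ELEMENT_FEATURES
                },
                "n_unpaired": fv.n_unpaired,
                "hb_index": round(fv.hb_index, 4),
            }
        )
    return features, log_records


def _site_start(fv, sirna, mrna) -> int:
    from .site_features import locate_site

    return locate_site(sirna, mrna).start


# ---------------------------------------------------------------------------
# Statistics on the feature table
# ---------------------------------------------------------------------------


def features_frame(features: List[SiteFeatureVector]) -> pd.DataFrame:
    rows = []
    for fv in features:
        row = {c: getattr(fv, c) for c in FEATURE_COLUMNS if c != "runs"}
        row["runs"] = ",".join(str(r) for r in fv.runs)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))


def _fmt(x: float) -> str:
    return f"{x:.4f}"


def _safe_univariable(y, x, robust, name) -> dict:
    try:
        res = logistic_univariable(y, x, robust=robust, name=name)
        row = next(iter(res.as_rows()))
        return {
            "predictor": name,
            "odds_ratio": _fmt(row["odds_ratio"]),
            "ci_low": _fmt(row["ci_low"]),
            "ci_high": _fmt(row["ci_high"]),
            "p_value": _fmt(row["p_value"]),
            "note": "",
        }
    except (ValueError, SeparationError) as exc:
        return {
            "predictor": name,
            "odds_ratio": "NA",
            "ci_low": "NA",
            "ci_high": "NA",
            "p_value": "NA",
            "note": str(exc),
        }


def tabulate_unpaired_by_structure(df: pd.DataFrame) -> pd.DataFrame:
    """siRNA counts by targeted bases per element class and group.

    Rows are base counts 0..max observed (zero rows retained), columns
    element class x group.  Because non-stem site bases are unpaired, the
    per-element base count is the unpaired-base count for every loop
    class; for the stem column it is the (paired) stem base count.  A
    single siRNA contributes to every element class, so column totals are
    not bounded by the group size.
    """
    max_count = int(df[list(ELEMENT_FEATURES)].to_numpy().max()) if len(df) else 0
    rows = []
    for u in range(0, max_count + 1):
        row = {"bases": u}
        for col in ELEMENT_FEATURES:
            for code, grp in ((1, "VH"), (0, "L")):
                sub = df[df["efficacy_code"] == code]
                row[f"{col}_{grp}"] = int((sub[col] == u).sum())
        rows.append(row)
    return pd.DataFrame(rows)


def _hist_by_group(df: pd.DataFrame, values_for) -> pd.DataFrame:
    """Histogram table value x group from a per-row value extractor."""
    per_group = {"VH": {}, "L": {}}
    for _, row in df.iterrows():
        grp = "VH" if row["efficacy_code"] == 1 else "L"
        for v in values_for(row):
            per_group[grp][v] = per_group[grp].get(v, 0) + 1
    all_vals = sorted(set(per_group["VH"]) | set(per_group["L"]))
    hi = all_vals[-1] if all_vals else 0
    rows = []
    for v in range(0, hi + 1):
        rows.append(
            {"value": v, "VH": per_group["VH"].get(v, 0), "L": per_group["L"].get(v, 0)}
        )
    return pd.DataFrame(rows)


def analyze_features(
    df: pd.DataFrame,
    hb_cutpoint: float = 25.0,
    robust: bool = True,
    normality_rule: str = "shapiro",
) -> Dict[str, pd.DataFrame]:
    """The full statistical battery as a pure function of the feature table."""
    if df.empty:
        raise ValueError("empty feature table")
    y = df["efficacy_code"].to_numpy()
    out: Dict[str, pd.DataFrame] = {}

    # --- element logistic regressions ------------------------------------
    uni_rows = [
        _safe_univariable(y, df[c].to_numpy(), robust, c) for c in ELEMENT_FEATURES
    ]
    for r in uni_rows:
        r["model"] = "univariable"
    try:
        X_elem = df[list(ELEMENT_FEATURES)].to_numpy()
        multi_note = ""
        try:
            multi = logistic_multivariable(
                y, X_elem, names=list(ELEMENT_FEATURES), robust=robust
            )
        except RankDeficiencyError:
            # element counts partition the site, so with fixed-length
            # guides the constant lies in their span: absorb the intercept
            multi = logistic_multivariable(
                y, X_elem, names=list(ELEMENT_FEATURES), robust=robust,
                intercept=False,
            )
            multi_note = "intercept absorbed (element counts are compositional)"
        multi_rows = [
            {
                "predictor": row["predictor"],
                "odds_ratio": _fmt(row["odds_ratio"]),
                "ci_low": _fmt(row["ci_low"]),
                "ci_high": _fmt(row["ci_high"]),
                "p_value": _fmt(row["p_value"]),
                "note": multi_note,
                "model": "multivariable",
            }
            for row in multi.as_rows()
        ]
    except (ValueError, SeparationError, RankDeficiencyError) as exc:
        multi_rows = [
            {
                "predictor": c,
                "odds_ratio": "NA",
                "ci_low": "NA",
                "ci_high": "NA",
                "p_value": "NA",
                "note": str(exc),
                "model": "multivariable",
            }
            for c in ELEMENT_FEATURES
        ]
    out["logistic_elements"] = pd.DataFrame(
        uni_rows + multi_rows,
        columns=["model", "predictor", "odds_ratio", "ci_low", "ci_high", "p_value", "note"],
    )

    # --- other univariable predictors ------------------------------------
    other_rows = [
        _safe_univariable(y, df[c].to_numpy(), robust, c) for c in OTHER_PREDICTORS
    ]
    accessible = (df["hb_index"] < hb_cutpoint).astype(float).to_numpy()
    other_rows.append(
        _safe_univariable(y, accessible, robust, f"hb_below_{hb_cutpoint:g}")
    )
    out["logistic_other"] = pd.DataFrame(
        other_rows,
        columns=["predictor", "odds_ratio", "ci_low", "ci_high", "p_value", "note"],
    )

    # --- distribution tables ---------------------------------------------
    out["unpaired_by_element"] = tabulate_unpaired_by_structure(df)
    out["unpaired_hist"] = _hist_by_group(df, lambda row: [int(row["n_unpaired"])])
    out["runs_hist"] = _hist_by_group(
        df,
        lambda row: [int(v) for v in str(row["runs"]).split(",") if v != ""],
    )

    # --- group comparisons ------------------------------------------------
    comp_rows = []
    a = df[df["efficacy_code"] == 1]
    b = df[df["efficacy_code"] == 0]
    for c in COMPARED_PREDICTORS:
        try:
            cmp_ = two_group_compare(
                a[c].to_numpy(), b[c].to_numpy(), normality_rule=normality_rule
            )
            vh_str, l_str = cmp_.format_mean_sd()
            comp_rows.append(
                {
                    "predictor": c,
                    "VH": vh_str,
                    "L": l_str,
                    "test": cmp_.test,
                    "statistic": _fmt(cmp_.statistic),
                    "p_value": _fmt(cmp_.p_value),
                    "note": "",
                }
            )
        except ValueError as exc:
            comp_rows.append(
                {
                    "predictor": c,
                    "VH": "NA",
                    "L": "NA",
                    "test": "NA",
                    "statistic": "NA",
                    "p_value": "NA",
                    "note": str(exc),
                }
            )
    out["group_comparisons"] = pd.DataFrame(
        comp_rows,
        columns=["predictor", "VH", "L", "test", "statistic", "p_value", "note"],
    )

    # --- GC content --------------------------------------------------------
    binning = thermo.DEFAULT_GC_BINNING
    bins = df["gc_percent"].map(lambda g: thermo.gc_bin(float(g), binning))
    df_gc = df.assign(
        gc_main=[m for m, _ in bins], gc_sub=[s if s else "none" for _, s in bins]
    )
    gc_rows = []
    for code, grp in ((1, "VH"), (0, "L")):
        sub = df_gc[df_gc["efficacy_code"] == code]
        row = {"group": grp, "n": len(sub)}
        for lbl in binning.main_labels():
            row[lbl] = int((sub["gc_main"] == lbl).sum())
        for lo, hi in binning.subgroups:
            lbl = binning.subgroup_label(lo, hi)
            row[lbl] = int((sub["gc_sub"] == lbl).sum())
        gc_rows.append(row)
    out["gc_bins"] = pd.DataFrame(gc_rows)

    mid_label = binning.main_labels()[1]
    in_range = (df_gc["gc_main"] == mid_label).to_numpy(dtype=bool)
    vh_mask = (df_gc["efficacy_code"] == 1).to_numpy(dtype=bool)
    table22 = [
        [int((in_range & vh_mask).sum()), int((~in_range & vh_mask).sum())],
        [int((in_range & ~vh_mask).sum()), int((~in_range & ~vh_mask).sum())],
    ]
    test_rows = [
        {
            "test": f"fisher_gc_{mid_label}",
            "statistic": "NA",
            "p_value": _fmt(fisher_exact_2x2(table22)),
            "note": f"VH {table22[0]}, L {table22[1]}",
        }
    ]
    sub_labels = [binning.subgroup_label(lo, hi) for lo, hi in binning.subgroups]
    sub_table = []
    for code in (1, 0):
        subdf = df_gc[df_gc["efficacy_code"] == code]
        sub_table.append([int((subdf["gc_sub"] == lbl).sum()) for lbl in sub_labels])
    try:
        stat, p = chi_square_rxc(np.array(sub_table).T)
        test_rows.append(
            {
                "test": "chi_square_gc_subgroups",
                "statistic": _fmt(stat),
                "p_value": _fmt(p),
                "note": "",
            }
        )
    except ValueError as exc:
        test_rows.append(
            {
                "test": "chi_square_gc_subgroups",
                "statistic": "NA",
                "p_value": "NA",
                "note": str(exc),
            }
        )
    n_vh = int(vh_mask.sum())
    successes = int((in_range & vh_mask).sum())
    if n_vh > 0:
        test_rows.append(
            {
                "test": "binomial_vh_in_range_vs_0.517",
                "statistic": f"{successes}/{n_vh}",
                "p_value": _fmt(one_sample_proportion(successes, n_vh, 0.517)),
                "note": "",
            }
        )
    # accessibility dichotomy at the H-b cut-point
    acc = (df_gc["hb_index"] < hb_cutpoint).to_numpy(dtype=bool)
    acc_table = [
        [int((acc & vh_mask).sum()), int((~acc & vh_mask).sum())],
        [int((acc & ~vh_mask).sum()), int((~acc & ~vh_mask).sum())],
    ]
    test_rows.append(
        {
            "test": f"fisher_hb_below_{hb_cutpoint:g}",
            "statistic": "NA",
            "p_value": _fmt(fisher_exact_2x2(acc_table)),
            "note": f"VH {acc_table[0]}, L {acc_table[1]}",
        }
    )
    out["gc_tests"] = pd.DataFrame(
        test_rows, columns=["test", "statistic", "p_value", "note"]
    )
    return out


# ---------------------------------------------------------------------------
# Bundle writing
# ---------------------------------------------------------------------------


def write_bundle(
    outdir,
    features: List[SiteFeatureVector],
    analysis: Dict[str, pd.DataFrame],
    meta: dict,
    log_records: Optional[List[dict]] = None,
) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_feature_table(features, outdir / "features.tsv")
    for name, frame in analysis.items():
        frame.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    with open(outdir / "run_log.jsonl", "w") as fh:
        fh.write(json.dumps({"event": "meta", **meta}, sort_keys=True) + "\n")
        for rec in log_records or []:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    return outdir


def run_pipeline(config: RunConfig) -> Path:
    """Full run: read inputs, compute features, analyse, write the bundle."""
    config.validate_paths()
    if not config.fasta or not config.sirna_table:
        raise ValueError("run_pipeline requires fasta and sirna_table paths")
    mrnas = read_fasta(config.fasta)
    sirnas = read_sirna_table(config.sirna_table)
    if not sirnas:
        raise ValueError("stage validation: empty siRNA table")
    features, log_records = compute_features(mrnas, sirnas, config)
    if not features:
        raise ValueError("stage validation: no VH/L siRNAs to analyse")
    df = features_frame(features)
    analysis = analyze_features(
        df,
        hb_cutpoint=config.hb_cutpoint,
        robust=config.robust,
        normality_rule=config.normality_rule,
    )
    meta = {
        "package_version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "n_sirnas": len(features),
    }
    return write_bundle(config.outdir, features, analysis, meta, log_records)
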