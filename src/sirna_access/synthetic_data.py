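"""Synthetic siRNA studies with the statistical structure the analysis assumes.

The generator emulates a two-group retrospective design: for each drawn
siRNA a random mRNA is folded, a target window is chosen uniformly, the
guide is its reverse complement, the structural predictors are computed,
and the efficacy label is drawn from a logit model

    P(very high efficacy) = logit^-1(beta0 + beta * feature)

on one chosen feature.  ``beta = 0`` yields a null study (no true
association); draws are rejection-sampled until both groups reach their
quota, mirroring a fixed VH/L case-control design of 150 + 150 siRNAs.
mRNAs are tens of nucleotides long — a desk-scale stand-in that keeps the
internal folding engine practical — and carry no UTR/CDS composition bias.

All randomness flows through ``numpy.random.default_rng`` (PCG64), so a
seed fixes the study exactly.

For replicated simulations (type-I-error and power calibration) the
module provides a fast path: :func:`build_feature_pool` folds a pool of
mRNAs once and :func:`replicate_univariable` re-draws target windows and
labels from that pool per replicate, so a thousand replicates do not
require a thousand rounds of folding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import stats as sps
from scipy.special import expit

from .fold_engine import FoldParams, representative_ensemble
from .site_features import SiteFeatureVector, TargetSite, compute_site_features
from .stats import logistic_univariable
from .structure_io import MrnaRecord, SirnaRecord, reverse_complement
from . import thermo

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGU"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the synthetic generator.

    ``n_per_group`` siRNAs per efficacy group (VH and L); ``mrna_length``
    is an inclusive length range in nt; ``gc_composition`` the per-base
    G+C probability; ``beta`` the log-odds of very-high efficacy per unit
    of ``effect_feature`` (0 = null); ``beta0`` the intercept, or ``None``
    to centre the labels at 50/50 around the feature's mean; ``seed``
    drives every random choice.
    """

    n_per_group: int = 150
    mrna_length: Tuple[int, int] = (50, 120)
    gc_composition: float = 0.5
    guide_length: int = 19
    effect_feature: str = "n_unpaired"
    beta: float = 0.0
    beta0: Optional[float] = None
    seed: int = 0
    max_draws: int = 1_000_000
    max_sirnas_per_mrna: int = 1
    ensemble_windows: int = 4
    fold_params: FoldParams = field(default_factory=FoldParams)

    def __post_init__(self) -> None:
        if self.n_per_group < 10:
            raise ValueError("n_per_group must be >= 10")
        lo, hi = self.mrna_length
        if not (1 <= lo <= hi):
            raise ValueError("invalid mRNA length range")
        if not 19 <= self.guide_length <= 21:
            raise ValueError("guide length must be 19-21 nt")
        if lo < self.guide_length:
            raise ValueError("mRNAs must be at least one guide length long")
        if not 0.0 <= self.gc_composition <= 1.0:
            raise ValueError("gc_composition must lie in [0, 1]")
        if self.max_sirnas_per_mrna not in (1, 2):
            raise ValueError("at most two siRNAs per mRNA are supported")


@dataclass
class Study:
    """A complete (synthetic or curated) two-group siRNA study."""

    mrnas: List[MrnaRecord]
    sirnas: List[SirnaRecord]
    sites: List[TargetSite]
    features: List[SiteFeatureVector]
    config: Optional[SyntheticConfig] = None
    diagnostics: dict = field(default_factory=dict)


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def generate_mrnas(
    config: SyntheticConfig, n: int, rng: Optional[np.random.Generator] = None
) -> List[MrnaRecord]:
    """``n`` i.i.d. random mRNAs at the configured GC composition."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    probs = _base_probs(config.gc_composition)
    lo, hi = config.mrna_length
    records = []
    for k in range(1, n + 1):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_BASES, size=length, p=probs))
        records.append(MrnaRecord(id=f"SYN{k:05d}", sequence=seq))
    return records


def _feature_value(fields: dict, name: str) -> float:
    if name not in fields:
        raise ValueError(f"unknown effect feature {name!r}")
    value = fields[name]
    if isinstance(value, tuple):
        raise ValueError(f"effect feature {name!r} is not scalar")
    return float(value)


def _auto_beta0(config: SyntheticConfig, mean_feature: float) -> float:
    if config.beta0 is not None:
        return config.beta0
    return -config.beta * mean_feature


def generate_study(config: SyntheticConfig) -> Study:
    """Draw a full synthetic study (folding every sampled mRNA).

    Draws are accepted into the VH (y=1) or L (y=0) group until both
    reach ``n_per_group``; draws for a full group are discarded.  Raises
    if the quotas are unreachable within ``max_draws``.
    """
    rng = np.random.default_rng(config.seed)
    nn_params = thermo.default_nn_params()
    probs = _base_probs(config.gc_composition)
    lo, hi = config.mrna_length
    g = config.guide_length

    # pilot to centre the intercept when beta0 is unspecified
    if config.beta0 is None and config.beta != 0.0:
        pilot_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(1,))
        )
        pilot_vals = []
        for _ in range(25):
            length = int(pilot_rng.integers(lo, hi + 1))
            seq = "".join(pilot_rng.choice(_BASES, size=length, p=probs))
            mrna = MrnaRecord(id="PILOT", sequence=seq)
            ensemble = representative_ensemble(
                seq, config.fold_params, config.ensemble_windows
            )
            start = int(pilot_rng.integers(1, length - g + 2))
            guide = reverse_complement(seq[start - 1 : start - 1 + g])
            _, fields = compute_site_features(
                guide, mrna, ensemble, fold_params=config.fold_params,
                nn_params=nn_params,
            )
            pilot_vals.append(_feature_value(fields, config.effect_feature))
        beta0 = _auto_beta0(config, float(np.mean(pilot_vals)))
    else:
        beta0 = config.beta0 if config.beta0 is not None else 0.0

    mrnas: List[MrnaRecord] = []
    sirnas: List[SirnaRecord] = []
    sites: List[TargetSite] = []
    features: List[SiteFeatureVector] = []
    n_vh = n_l = 0
    draws = 0
    while (n_vh < config.n_per_group or n_l < config.n_per_group):
        if draws >= config.max_draws:
            raise RuntimeError(
                f"group quotas unreachable within {config.max_draws} draws "
                f"(VH={n_vh}, L={n_l}); check beta0/beta"
            )
        draws += 1
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_BASES, size=length, p=probs))
        mrna_id = f"M{draws:06d}"
        mrna = MrnaRecord(id=mrna_id, sequence=seq)
        ensemble = representative_ensemble(
            seq, config.fold_params, config.ensemble_windows
        )
        start = int(rng.integers(1, length - g + 2))
        guide = reverse_complement(seq[start - 1 : start - 1 + g])
        sirna_id = f"S{draws:06d}"
        site, fields = compute_site_features(
            guide, mrna, ensemble, fold_params=config.fold_params,
            nn_params=nn_params, sirna_id=sirna_id,
        )
        x = _feature_value(fields, config.effect_feature)
        p = float(expit(beta0 + config.beta * x))
        y = int(rng.random() < p)
        if y == 1:
            if n_vh >= config.n_per_group:
                continue
            n_vh += 1
            percent = 90.0 + 10.0 * rng.random()
        else:
            if n_l >= config.n_per_group:
                continue
            n_l += 1
            percent = 50.0 * rng.random()
        sirna = SirnaRecord(
            id=sirna_id, guide=guide, target_id=mrna_id, efficacy_percent=percent
        )
        mrnas.append(mrna)
        sirnas.append(sirna)
        sites.append(site)
        features.append(
            SiteFeatureVector(sirna_id=sirna_id, efficacy_code=y, **fields)
        )

    study = Study(
        mrnas=mrnas, sirnas=sirnas, sites=sites, features=features, config=config
    )
    # exchangeability sanity check under the null (logged, never asserted)
    xs = np.array([_feature_value(f.__dict__, config.effect_feature) for f in features])
    ys = np.array([f.efficacy_code for f in features])
    if np.unique(xs[ys == 1]).size > 1 and np.unique(xs[ys == 0]).size > 1:
        ks = sps.ks_2samp(xs[ys == 1], xs[ys == 0])
        study.diagnostics["ks_feature_p"] = float(ks.pvalue)
        logger.info(
            "KS test of %s between groups: p=%.3f", config.effect_feature, ks.pvalue
        )
    study.diagnostics["n_draws"] = draws
    study.diagnostics["beta0"] = beta0
    return study


# ---------------------------------------------------------------------------
# Fast path for replicated simulations
# ---------------------------------------------------------------------------


@dataclass
class FeaturePool:
    """Pre-folded mRNAs with per-position prefix sums for window features.

    Folding is the expensive step of study generation; the pool performs
    it once so that replicated simulations only re-draw target windows and
    labels.  ``unpaired_csum[i, k]`` is the number of unpaired positions
    among the first k nucleotides of mRNA i (optimal fold);
    ``hb_csum`` accumulates the per-position H-b contributions.
    """

    config: SyntheticConfig
    lengths: np.ndarray
    n_starts: np.ndarray
    unpaired_csum: np.ndarray
    hb_csum: np.ndarray

    @property
    def size(self) -> int:
        return len(self.lengths)


def build_feature_pool(
    config: SyntheticConfig, n_mrnas: int = 200, seed: Optional[int] = None
) -> FeaturePool:
    """Fold ``n_mrnas`` random mRNAs once for reuse across replicates."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    probs = _base_probs(config.gc_composition)
    lo, hi = config.mrna_length
    lengths = rng.integers(lo, hi + 1, size=n_mrnas)
    lmax = int(lengths.max())
    unpaired_csum = np.zeros((n_mrnas, lmax + 1))
    hb_csum = np.zeros((n_mrnas, lmax + 1))
    for i in range(n_mrnas):
        n = int(lengths[i])
        seq = "".join(rng.choice(_BASES, size=n, p=probs))
        ensemble = representative_ensemble(
            seq, config.fold_params, config.ensemble_windows
        )
        opt = ensemble.optimal
        unp = np.array([1.0 if opt.pairs[k] == 0 else 0.0 for k in range(1, n + 1)])
        unpaired_csum[i, 1 : n + 1] = np.cumsum(unp)
        from .fold_engine import ss_count as _ssc

        ss = _ssc(ensemble)
        bonds = np.array([3.0 if c in "GC" else 2.0 for c in seq])
        contrib = (1.0 - np.array(ss.counts[1:]) / ss.n_structures) * bonds
        hb_csum[i, 1 : n + 1] = np.cumsum(contrib)
    return FeaturePool(
        config=config,
        lengths=lengths,
        n_starts=lengths - config.guide_length + 1,
        unpaired_csum=unpaired_csum,
        hb_csum=hb_csum,
    )


def _draw_pool_features(
    pool: FeaturePool, rng: np.random.Generator, size: int, feature: str
) -> np.ndarray:
    idx = rng.integers(0, pool.size, size=size)
    s0 = rng.integers(0, pool.n_starts[idx])  # 0-based window starts
    g = pool.config.guide_length
    if feature == "n_unpaired":
        csum = pool.unpaired_csum
    elif feature == "hb_index":
        csum = pool.hb_csum
    else:
        raise ValueError(
            f"feature {feature!r} not supported by the pooled fast path"
        )
    return csum[idx, s0 + g] - csum[idx, s0]


def replicate_univariable(
    config: SyntheticConfig,
    n_replicates: int,
    base_seed: int,
    pool: Optional[FeaturePool] = None,
    pool_size: int = 200,
    robust: bool = True,
):
    """Repeated synthetic studies, each reduced to its univariable fit.

    Returns a pandas DataFrame with one row per replicate: log_or, se,
    odds_ratio, ci_low, ci_high, p_value, n.  Replicate r uses the
    independent seeded stream ``default_rng([base_seed, r])``; the
    intercept is centred so the two groups are reachable.
    """
    import pandas as pd

    if pool is None:
        pool = build_feature_pool(config, n_mrnas=pool_size, seed=base_seed)
    feature = config.effect_feature
    pilot_rng = np.random.default_rng([base_seed, 987654321])
    pilot = _draw_pool_features(pool, pilot_rng, 4000, feature)
    beta0 = _auto_beta0(config, float(pilot.mean()))
    n_per = config.n_per_group
    rows = []
    for r in range(n_replicates):
        rng = np.random.default_rng([base_seed, r])
        xs = np.empty(0)
        ys = np.empty(0, dtype=bool)
        while True:
            batch = _draw_pool_features(pool, rng, 2 * n_per + 64, feature)
            p = expit(beta0 + config.beta * batch)
            y = rng.random(batch.size) < p
            xs = np.concatenate([xs, batch])
            ys = np.concatenate([ys, y])
            if (ys.sum() >= n_per) and ((~ys).sum() >= n_per):
                break
            if xs.size > config.max_draws:
                raise RuntimeError("group quotas unreachable; check beta0/beta")
        # sequential quota fill: a draw for a full group is discarded
        c1 = np.cumsum(ys)
        c0 = np.cumsum(~ys)
        keep = (ys & (c1 <= n_per)) | (~ys & (c0 <= n_per))
        x_kept = xs[keep]
        y_kept = ys[keep].astype(int)
        res = logistic_univariable(y_kept, x_kept, robust=robust, name=feature)
        rows.append(
            {
                "log_or": res.coef[0],
                "se": res.se[0],
                "odds_ratio": res.odds_ratio[0],
                "ci_low": res.ci_low[0],
                "ci_high": res.ci_high[0],
                "p_value": res.p_value[0],
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hand-curated fixture study
# ---------------------------------------------------------------------------

# Three short mRNAs whose maximum-weight folds are forced (G-C pairs only,
# A spacers), so the optimal structure can be checked by eye:
#   FIX1: 5' tail - stem - internal loop - stem - hairpin - 3' tail
#   FIX2: 5' tail - stem - 2-nt bulge - stem - one-base bulge - stem - hairpin
#   FIX3: 5' tail - stem - multibranch loop with two hairpins - 3' tail
_FIXTURE_MRNAS = (
    ("FIX1", "AAAGGGGGAAGGGGAAAACCCCAACCCCCAAA"),
    ("FIX2", "AAAGGGGAAGGGAGGAAAACCCCCCCCCAAA"),
    ("FIX3", "AAGGGGAGGGAAAACCCAGGGAAAACCCACCCCAA"),
)

# (sirna_id, mrna_id, site start, efficacy percent)
_FIXTURE_SITES = (
    ("FIXS1", "FIX1", 1, 95.0),
    ("FIXS2", "FIX1", 14, 20.0),
    ("FIXS3", "FIX2", 1, 92.0),
    ("FIXS4", "FIX2", 13, 35.0),
    ("FIXS5", "FIX3", 3, 98.0),
    ("FIXS6", "FIX3", 17, 10.0),
)

_FIXTURE_GUIDE_LEN = 19


def fixture_study() -> Study:
    """A small curated six-siRNA study exercising every element class.

    The three mRNAs admit a unique maximum-weight fold (only G-C pairs are
    possible and the pairing blocks nest in one way), so the annotations
    were checked by hand against the designed structures.  Deterministic:
    repeated calls produce identical output.
    """
    nn_params = thermo.default_nn_params()
    params = FoldParams()
    mrnas = [MrnaRecord(id=i, sequence=s) for i, s in _FIXTURE_MRNAS]
    by_id = {m.id: m for m in mrnas}
    ensembles = {
        m.id: representative_ensemble(m.sequence, params, n_windows=4) for m in mrnas
    }
    sirnas: List[SirnaRecord] = []
    sites: List[TargetSite] = []
    features: List[SiteFeatureVector] = []
    for sid, mid, start, percent in _FIXTURE_SITES:
        mrna = by_id[mid]
        site_seq = mrna.sequence[start - 1 : start - 1 + _FIXTURE_GUIDE_LEN]
        guide = reverse_complement(site_seq)
        sirna = SirnaRecord(
            id=sid, guide=guide, target_id=mid, efficacy_percent=percent
        )
        site, fields = compute_site_features(
            guide, mrna, ensembles[mid], fold_params=params, nn_params=nn_params,
            sirna_id=sid,
        )
        fv = SiteFeatureVector(
            sirna_id=sid,
            efficacy_code=1 if sirna.efficacy_class == "VH" else 0,
            **fields,
        )
        sirnas.append(sirna)
        sites.append(site)
        features.append(fv)
    return Study(mrnas=mrnas, sirnas=sirnas, sites=sites, features=features)
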