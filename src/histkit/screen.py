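"""Enrichment statistics for pooled FACS-bin (sort-seq) histone screens.

A screen expresses a library of histone constructs, bins cells at the top and
bottom 10% of a chromatin signal (or compares timepoints for proliferation
screens), and sequences each bin.  Per construct we test whether its abundance
differs between conditions using a negative-binomial model on raw counts:

* size factors are median-of-ratios factors computed on the spiked-in
  fluorescent-protein control constructs (GFP/mCherry), so the normalization
  is anchored on constructs with no phenotype;
* per-construct dispersions are method-of-moments estimates shrunk toward a
  fitted mean-dispersion trend;
* the condition contrast is a Wald test on the log mean ratio (with a score
  test fallback when a condition's counts are all zero);
* Benjamini-Hochberg adjustment is applied across non-control constructs and
  hits are constructs with padj < 0.05, reported with their direction
  ("signed FDR").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .variants import SubstitutionVariant

LOG2 = np.log(2.0)

RESULT_COLUMNS = [
    "log2fc",
    "se",
    "pvalue",
    "padj",
    "signed_fdr",
    "signed_log_padj",
    "is_control",
]


@dataclass
class ScreenCountTable:
    """Construct x sample integer counts with sample metadata.

    ``counts`` is indexed by construct id with one column per sample;
    ``sample_meta`` is indexed by sample name with columns ``replicate`` and
    ``condition`` (e.g. ``high_bin``/``low_bin`` or ``t0``/``t14``);
    ``control_ids`` flags phenotype-neutral control constructs.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    control_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be non-negative integers")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        unknown = set(self.control_ids) - set(self.counts.index)
        if unknown:
            raise ValueError(f"control ids not in counts: {sorted(unknown)}")

    @property
    def construct_ids(self) -> list[str]:
        return list(self.counts.index)

    def condition_samples(self, condition: str) -> list[str]:
        meta = self.sample_meta.loc[list(self.counts.columns)]
        return list(meta.index[meta["condition"] == condition])


class Concordance(NamedTuple):
    r2: float
    r: float
    n: int


def count_exact_matches(
    reads: Iterable[str],
    barcode_map: Mapping[str, str],
    library_seqs: Mapping[str, str],
    sample_meta: pd.DataFrame | None = None,
    control_ids: list[str] | None = None,
) -> tuple[ScreenCountTable, dict[str, int]]:
    """Tally reads into a count table under a zero-mismatch policy.

    A read contributes one count iff its leading barcode matches a sample
    barcode exactly and the remainder matches a library construct sequence
    exactly; all other reads are discarded with a tallied reason.  This
    mirrors stringent 0-error demultiplexing and variant calling.
    """
    barcodes = list(barcode_map)
    if len(set(barcodes)) != len(barcodes) or len(set(barcode_map.values())) != len(
        barcodes
    ):
        raise ValueError("barcodes and sample names must be unique")
    bc_lens = {len(b) for b in barcodes}
    if len(bc_lens) != 1:
        raise ValueError("barcodes must share a fixed length")
    (bc_len,) = bc_lens
    seq_to_construct: dict[str, str] = {}
    for cid, seq in library_seqs.items():
        if seq in seq_to_construct:
            raise ValueError(f"library sequences not unique: {cid}")
        seq_to_construct[seq] = cid

    samples = list(barcode_map.values())
    counts = pd.DataFrame(
        0, index=list(library_seqs), columns=samples, dtype=np.int64
    )
    discards = {"undemultiplexed": 0, "unmatched_insert": 0}
    for read in reads:
        sample = barcode_map.get(read[:bc_len])
        if sample is None:
            discards["undemultiplexed"] += 1
            continue
        construct = seq_to_construct.get(read[bc_len:])
        if construct is None:
            discards["unmatched_insert"] += 1
            continue
        counts.loc[construct, sample] += 1
    if sample_meta is None:
        sample_meta = pd.DataFrame(
            {"replicate": samples, "condition": ["unknown"] * len(samples)},
            index=samples,
        )
    table = ScreenCountTable(counts, sample_meta, control_ids or [])
    return table, discards


def control_size_factors(
    table: ScreenCountTable, rows: list[str] | None = None
) -> pd.Series:
    """Median-of-ratios size factors computed on control rows only.

    factor_j = median over usable controls i of counts[i, j] / geomean_i,
    where geomean_i is the geometric mean of row i across samples.  Rows
    containing a zero have no finite geometric-mean ratio and are skipped.
    """
    if rows is None:
        rows = table.control_ids
    if not rows:
        raise ValueError("no control rows supplied for size-factor estimation")
    sub = table.counts.loc[rows].to_numpy(dtype=float)
    usable = (sub > 0).all(axis=1)
    if not usable.any():
        raise ValueError("every control row contains a zero; size factors undefined")
    sub = sub[usable]
    log_geomean = np.log(sub).mean(axis=1, keepdims=True)
    ratios = sub / np.exp(log_geomean)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=table.counts.columns, name="size_factor")


def _normalized(table: ScreenCountTable, factors: pd.Series) -> np.ndarray:
    return table.counts.to_numpy(dtype=float) / factors.loc[table.counts.columns].to_numpy()


def estimate_dispersion(
    table: ScreenCountTable,
    factors: pd.Series,
    conditions: tuple[str, str] | None = None,
    prior_weight: float = 0.75,
    clip: tuple[float, float] = (1e-8, 10.0),
) -> pd.Series:
    """Per-construct NB dispersion: method of moments shrunk toward a trend.

    Raw per-construct estimates pool within-condition variances of normalized
    counts; a mean-dispersion trend a0 + a1/mu is fit by least squares with
    one outlier-clipping pass, and each construct's dispersion is a weighted
    average of its raw estimate and the trend value, clipped to ``clip``.
    """
    if conditions is None:
        conds = list(dict.fromkeys(table.sample_meta["condition"]))
        if len(conds) != 2:
            raise ValueError("two conditions required")
        conditions = (conds[0], conds[1])
    sf = factors.loc[table.counts.columns].to_numpy()
    y = _normalized(table, factors)

    raw_num = np.zeros(y.shape[0])
    raw_den = 0.0
    mu = y.mean(axis=1)
    for cond in conditions:
        cols = [
            i
            for i, s in enumerate(table.counts.columns)
            if table.sample_meta.loc[s, "condition"] == cond
        ]
        if len(cols) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 replicates")
        yc = y[:, cols]
        mean_c = yc.mean(axis=1)
        var_c = yc.var(axis=1, ddof=1)
        # Var(K/s) = m/s + alpha m^2  =>  alpha = (var - m*mean(1/s)) / m^2
        inv_s = np.mean(1.0 / sf[cols])
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_c = (var_c - mean_c * inv_s) / np.square(mean_c)
        alpha_c = np.where(mean_c > 0, alpha_c, 0.0)
        df = len(cols) - 1
        raw_num += df * alpha_c
        raw_den += df
    alpha_raw = raw_num / raw_den

    # trend fit alpha ~ a0 + a1/mu on all constructs, one sigma-clip pass
    ok = mu > 0
    x = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    t = alpha_raw[ok]
    coef, *_ = np.linalg.lstsq(x, t, rcond=None)
    resid = t - x @ coef
    keep = np.abs(resid) <= 3.0 * (np.std(resid) + 1e-12)
    if keep.sum() >= 2:
        coef, *_ = np.linalg.lstsq(x[keep], t[keep], rcond=None)
    coef = np.maximum(coef, 0.0)
    trend = np.full_like(alpha_raw, clip[0])
    trend[ok] = coef[0] + coef[1] / mu[ok]

    alpha = (1.0 - prior_weight) * np.maximum(alpha_raw, 0.0) + prior_weight * trend
    alpha = np.clip(alpha, clip[0], clip[1])
    return pd.Series(alpha, index=table.counts.index, name="dispersion")


def _group_mean(y: np.ndarray, cols: list[int]) -> np.ndarray:
    return y[:, cols].mean(axis=1)


def test_enrichment(
    table: ScreenCountTable,
    contrast: tuple[str, str] = ("high_bin", "low_bin"),
    factors: pd.Series | None = None,
    dispersion: pd.Series | float | None = None,
    alpha_clip: tuple[float, float] = (1e-8, 10.0),
) -> pd.DataFrame:
    """Per-construct NB Wald test of the condition contrast.

    ``contrast = (numerator, denominator)``: positive log2fc means enrichment
    in the numerator condition (high bin, or t14).  Group means are unweighted
    means of control-normalized counts; a 0.5 display pseudocount (on the
    normalized scale) enters log2fc only when a group mean is exactly zero and
    never enters the test statistic.  Controls are excluded from BH adjustment
    and carry padj = NaN.

    Returns a DataFrame indexed by construct with columns ``log2fc, se,
    pvalue, padj, signed_fdr, signed_log_padj, is_control``; the contrast and
    sign convention are recorded in ``result.attrs``.
    """
    cond_hi, cond_lo = contrast
    cols = list(table.counts.columns)
    meta = table.sample_meta.loc[cols]
    hi = [i for i, s in enumerate(cols) if meta.loc[s, "condition"] == cond_hi]
    lo = [i for i, s in enumerate(cols) if meta.loc[s, "condition"] == cond_lo]
    if not hi or not lo:
        raise ValueError(f"degenerate design: conditions {contrast} not both present")

    if factors is None:
        if table.control_ids:
            factors = control_size_factors(table)
        else:
            warnings.warn("no controls: size factors computed on all constructs")
            factors = control_size_factors(table, rows=table.construct_ids)
    sf = factors.loc[cols].to_numpy()
    y = _normalized(table, factors)
    K = table.counts.to_numpy(dtype=float)

    if dispersion is None:
        alpha = estimate_dispersion(table, factors, conditions=contrast).to_numpy()
    elif np.isscalar(dispersion):
        alpha = np.full(y.shape[0], float(dispersion))
    else:
        alpha = dispersion.loc[table.counts.index].to_numpy()
    alpha = np.clip(alpha, alpha_clip[0], alpha_clip[1])

    m_hi = _group_mean(y, hi)
    m_lo = _group_mean(y, lo)

    # display log2fc; pseudocount only where a group mean is exactly zero
    eps = 0.5 * np.mean(1.0 / sf)
    with np.errstate(divide="ignore"):
        l2 = (np.log(m_hi) - np.log(m_lo)) / LOG2
    zero = (m_hi == 0) | (m_lo == 0)
    l2[zero] = (np.log(m_hi[zero] + eps) - np.log(m_lo[zero] + eps)) / LOG2

    def _info(m: np.ndarray, cols_: list[int]) -> np.ndarray:
        mu = m[:, None] * sf[None, cols_]
        return (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        info_hi = _info(m_hi, hi)
        info_lo = _info(m_lo, lo)
        var_beta = 1.0 / info_hi + 1.0 / info_lo
        z_wald = (np.log(m_hi) - np.log(m_lo)) / np.sqrt(var_beta)
        se = np.sqrt(var_beta) / LOG2

    # score-test fallback where the Wald statistic degenerates (a zero group)
    m0 = y.mean(axis=1)
    mu0 = m0[:, None] * sf[None, :]
    w = mu0 / (1.0 + alpha[:, None] * mu0)
    resid = (K - mu0) / (1.0 + alpha[:, None] * mu0)
    U = resid[:, hi].sum(axis=1)
    w_hi = w[:, hi].sum(axis=1)
    w_all = w.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        V = w_hi - np.square(w_hi) / w_all
        z_score = np.where(V > 0, U / np.sqrt(V), 0.0)

    z = np.where(np.isfinite(z_wald), z_wald, z_score)
    z = np.where((m_hi == 0) & (m_lo == 0), 0.0, z)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))

    res = pd.DataFrame(
        {
            "log2fc": l2,
            "se": se,
            "pvalue": pvalue,
            "padj": np.nan,
            "signed_fdr": np.nan,
            "signed_log_padj": np.nan,
            "is_control": [cid in set(table.control_ids) for cid in table.counts.index],
        },
        index=table.counts.index,
    )
    mask = ~res["is_control"].to_numpy()
    if mask.any():
        padj = bh_adjust(res.loc[mask, "pvalue"].to_numpy())
        res.loc[mask, "padj"] = padj
        sign = np.sign(res.loc[mask, "log2fc"].to_numpy())
        res.loc[mask, "signed_fdr"] = sign * padj
        with np.errstate(divide="ignore"):
            res.loc[mask, "signed_log_padj"] = sign * (-np.log10(padj))
    res.attrs["contrast"] = contrast
    res.attrs["sign_convention"] = f"positive log2fc = enriched in {cond_hi}"
    return res


test_enrichment.__test__ = False  # not a pytest test


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_hits(result: pd.DataFrame, alpha: float = 0.05) -> dict[str, set[str]]:
    """Constructs with padj strictly below alpha, split by direction."""
    usable = result[~result["is_control"].astype(bool)] if "is_control" in result else result
    sig = usable[usable["padj"] < alpha]
    return {
        "enriched": set(sig.index[sig["log2fc"] > 0]),
        "depleted": set(sig.index[sig["log2fc"] < 0]),
    }


def replicate_concordance(resA: pd.DataFrame, resB: pd.DataFrame) -> Concordance:
    """Squared Pearson correlation of per-construct log2fc across replicates."""
    shared = resA.index.intersection(resB.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared constructs")
    a = resA.loc[shared, "log2fc"].to_numpy(dtype=float)
    b = resB.loc[shared, "log2fc"].to_numpy(dtype=float)
    r = float(np.corrcoef(a, b)[0, 1])
    return Concordance(r2=r * r, r=r, n=len(shared))


def call_role_switchers(
    resA: pd.DataFrame, resB: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Classify constructs by behavior change between two backgrounds.

    ``switcher``: significant (padj < alpha) in either background and the
    log2fc sign flips between them.  ``stable_hit``: significant in either,
    same sign.  Otherwise ``not_significant``.  Rows are ranked by
    log2fc_B - log2fc_A (descending).
    """
    shared = resA.index.intersection(resB.index)
    out = pd.DataFrame(
        {
            "log2fc_A": resA.loc[shared, "log2fc"],
            "log2fc_B": resB.loc[shared, "log2fc"],
            "padj_A": resA.loc[shared, "padj"],
            "padj_B": resB.loc[shared, "padj"],
        },
        index=shared,
    )
    sig = (out["padj_A"] < alpha) | (out["padj_B"] < alpha)
    flip = np.sign(out["log2fc_A"]) != np.sign(out["log2fc_B"])
    status = np.where(sig & flip, "switcher", np.where(sig, "stable_hit", "not_significant"))
    out["status"] = status
    out["delta_log2fc"] = out["log2fc_B"] - out["log2fc_A"]
    return out.sort_values("delta_log2fc", ascending=False)


@dataclass
class DomainAnnotation:
    """Region labels over reference positions, e.g. tail vs globular domain."""

    regions: dict[str, tuple[int, int]]  # inclusive 1-based (start, end)

    def __post_init__(self) -> None:
        for name, (a, b) in self.regions.items():
            if b < a:
                raise ValueError(f"region {name}: end before start")

    def region_of(self, position: int) -> str:
        for name, (a, b) in self.regions.items():
            if a <= position <= b:
                return name
        raise KeyError(f"position {position} not covered by annotation")

    def length(self, name: str) -> int:
        a, b = self.regions[name]
        return b - a + 1


#: mature human H4: disordered tail then globular fold
H4_DOMAINS = DomainAnnotation({"tail": (1, 25), "globular": (26, 102)})


def positional_enrichment(
    hits: Iterable[SubstitutionVariant],
    annotation: DomainAnnotation,
    ratio_of: tuple[str, str] = ("tail", "globular"),
) -> pd.DataFrame:
    """Per-region hit density (hits per residue) and the tail/globular ratio."""
    counts = {name: 0 for name in annotation.regions}
    for h in hits:
        counts[annotation.region_of(h.position)] += 1
    rows = []
    dens = {}
    for name in annotation.regions:
        length = annotation.length(name)
        if length == 0:
            raise ValueError(f"zero-length region {name}")
        dens[name] = counts[name] / length
        rows.append({"region": name, "hits": counts[name], "length": length, "density": dens[name]})
    df = pd.DataFrame(rows).set_index("region")
    num, den = ratio_of
    if dens[den] == 0:
        if dens[num] == 0:
            warnings.warn("no hits in either region; ratio undefined")
            ratio = float("nan")
        else:
            ratio = float("inf")
    else:
        ratio = dens[num] / dens[den]
    df.attrs["ratio"] = ratio
    df.attrs["ratio_of"] = ratio_of
    return df


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def read_count_table(
    counts_path: str, samples_path: str, controls_path: str | None = None
) -> ScreenCountTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(samples_path, sep="\t", index_col=0)
    controls: list[str] = []
    if controls_path:
        with open(controls_path) as fh:
            controls = [line.strip() for line in fh if line.strip()]
    return ScreenCountTable(counts, meta, controls)


def write_result(result: pd.DataFrame, path: str, alpha: float = 0.05) -> None:
    out = result.copy()
    out["hit"] = (out["padj"] < alpha) & ~out["is_control"].astype(bool)
    out["direction"] = np.where(out["log2fc"] > 0, "enriched", "depleted")
    out.to_csv(path, sep="\t", index_label="construct")
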