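"""Synthetic sort-seq screens, homolog sets and variant effects.

The generator emulates the causal structure of a pooled FACS-bin screen:
every construct carries a latent phenotype shift delta (in SD units of the
within-construct cell-to-cell spread of the sorted signal), cells are gated
at the pooled population's low/high quantiles (top and bottom 10% by
default), and sequencing counts per bin are overdispersed (Gamma-Poisson)
around expectations proportional to library abundance times the construct's
gate probabilities.

Effects follow a sparse repressor model: a fraction ``pi`` of single mutants
are true repressors with shift ``delta_repressor`` (< 0: they lower the
signal, e.g. total H3K9me3); double mutants are additive in their parents
plus Gaussian epistasis noise of SD ``tau``.  A continuous mode draws
per-construct shifts from a normal distribution instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .screen import ScreenCountTable
from .variants import CANONICAL_AA, HomologRecord, ReferenceHistone, SubstitutionVariant


@dataclass
class EffectModel:
    """Latent-effect model for a variant library.

    ``pi``: fraction of single mutants that are true repressors;
    ``delta_repressor``: their phenotype shift (SD units, negative);
    ``tau``: SD of the epistasis deviation added to double mutants;
    ``continuous``: draw single effects from Normal(0, ``sigma_delta``)
    instead of the two-class point-mass model.
    """

    pi: float = 0.2
    delta_repressor: float = -1.5
    tau: float = 0.2
    continuous: bool = False
    sigma_delta: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


@dataclass
class ScreenSimConfig:
    """Sequencing/sorting configuration of a simulated screen."""

    depth: float = 1000.0  # mean reads per construct per bin
    phi: float = 0.05  # Gamma-Poisson overdispersion of counts
    gate_low: float = 0.10
    gate_high: float = 0.90
    abundance_sigma: float = 0.5  # lognormal spread of library representation
    replicates: int = 2
    n_controls: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not (0.0 < self.gate_low < self.gate_high < 1.0):
            raise ValueError("gates must satisfy 0 < low < high < 1")
        if self.phi < 0:
            raise ValueError("phi must be >= 0")


def simulate_effects(
    singles: list[str],
    pairs: list[tuple[str, str]],
    model: EffectModel,
    seed: int,
) -> dict[str, float]:
    """Draw latent shifts for singles and additive-plus-epistasis doubles.

    Double-mutant constructs are keyed ``"a+b"``.  Reproducible per seed.
    """
    rng = np.random.default_rng(seed)
    if model.continuous:
        delta_single = rng.normal(0.0, model.sigma_delta, size=len(singles))
    else:
        repressor = rng.random(len(singles)) < model.pi
        delta_single = np.where(repressor, model.delta_repressor, 0.0)
    effects = {name: float(d) for name, d in zip(singles, delta_single)}
    eps = rng.normal(0.0, model.tau, size=len(pairs)) if model.tau > 0 else np.zeros(len(pairs))
    for (a, b), e in zip(pairs, eps):
        effects[f"{a}+{b}"] = effects[a] + effects[b] + float(e)
    return effects


def pooled_gate_thresholds(
    deltas: np.ndarray, weights: np.ndarray, q_low: float, q_high: float
) -> tuple[float, float]:
    """Signal thresholds at the pooled population's q_low/q_high quantiles.

    The pooled signal is an abundance-weighted mixture of Normal(delta, 1)
    components; thresholds solve the mixture CDF = q.  With all deltas zero
    this reduces to the standard-normal quantiles.
    """
    w = weights / weights.sum()

    def cdf(z: float) -> float:
        return float(np.sum(w * stats.norm.cdf(z - deltas)))

    lo = float(deltas.min()) - 10.0
    hi = float(deltas.max()) + 10.0
    z_low = optimize.brentq(lambda z: cdf(z) - q_low, lo, hi)
    z_high = optimize.brentq(lambda z: cdf(z) - q_high, lo, hi)
    return z_low, z_high


def gate_probabilities(
    delta: np.ndarray, z_low: float, z_high: float
) -> tuple[np.ndarray, np.ndarray]:
    """P(cell of a construct falls in the low / high bin)."""
    p_low = stats.norm.cdf(z_low - delta)
    p_high = 1.0 - stats.norm.cdf(z_high - delta)
    return p_low, p_high


def simulate_screen_counts(
    effects: dict[str, float], config: ScreenSimConfig
) -> tuple[ScreenCountTable, pd.DataFrame]:
    """Simulate an overdispersed sort-seq count table from latent effects.

    Returns the count table (controls appended and flagged) and a
    ground-truth frame with each construct's delta and abundance.
    """
    rng = np.random.default_rng(config.seed)
    ids = list(effects)
    control_ids = [f"ctrl_{i:02d}" for i in range(config.n_controls)]
    all_ids = ids + control_ids
    delta = np.array([effects[c] for c in ids] + [0.0] * config.n_controls)
    abundance = rng.lognormal(0.0, config.abundance_sigma, size=len(all_ids))

    z_low, z_high = pooled_gate_thresholds(
        delta, abundance, config.gate_low, config.gate_high
    )
    p_low, p_high = gate_probabilities(delta, z_low, z_high)

    total_reads = config.depth * len(all_ids)
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for rep in range(1, config.replicates + 1):
        for cond, p in (("low_bin", p_low), ("high_bin", p_high)):
            share = abundance * p
            mu = total_reads * share / share.sum()
            if config.phi > 0:
                lam = rng.gamma(shape=1.0 / config.phi, scale=config.phi * mu)
            else:
                lam = mu
            name = f"rep{rep}_{cond}"
            cols[name] = rng.poisson(lam)
            meta_rows.append({"sample": name, "replicate": rep, "condition": cond})

    counts = pd.DataFrame(cols, index=all_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    table = ScreenCountTable(counts, meta, control_ids)
    truth = pd.DataFrame(
        {
            "delta": delta,
            "abundance": abundance,
            "is_control": [c in set(control_ids) for c in all_ids],
            "p_low": p_low,
            "p_high": p_high,
        },
        index=all_ids,
    )
    truth.attrs["z_low"] = z_low
    truth.attrs["z_high"] = z_high
    return table, truth


def simulate_homologs(
    reference: ReferenceHistone,
    n: int,
    per_position_sub_rate: float = 0.02,
    fragment_rate: float = 0.1,
    offlength_rate: float = 0.1,
    seed: int = 0,
) -> tuple[list[HomologRecord], dict[str, list[SubstitutionVariant]]]:
    """Generate homologs with planted substitutions, fragments and indels.

    Returns the records plus the ground-truth substitution list per record
    (fragments and off-length records map to an empty list: the nomination
    filters are expected to remove them).
    """
    for rate in (per_position_sub_rate, fragment_rate, offlength_rate):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    L = len(reference.sequence)
    records: list[HomologRecord] = []
    truth: dict[str, list[SubstitutionVariant]] = {}
    for i in range(n):
        rid = f"hom_{i:04d}"
        u = rng.random()
        if u < fragment_rate:
            cut = int(rng.integers(max(1, L // 4), L))
            records.append(
                HomologRecord(
                    id=rid,
                    sequence=reference.sequence[:cut],
                    description=f"{rid} histone {reference.family} (Fragment)",
                    is_fragment=True,
                )
            )
            truth[rid] = []
            continue
        if u < fragment_rate + offlength_rate:
            seq = list(reference.sequence)
            k = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                del seq[: k]
            else:
                seq = list(rng.choice(list(CANONICAL_AA), size=k)) + seq
            records.append(
                HomologRecord(
                    id=rid, sequence="".join(seq), description=f"{rid} histone {reference.family}"
                )
            )
            truth[rid] = []
            continue
        n_subs = rng.binomial(L, per_position_sub_rate)
        positions = sorted(rng.choice(L, size=n_subs, replace=False) + 1)
        seq = list(reference.sequence)
        variants = []
        for pos in positions:
            wt = reference.sequence[pos - 1]
            alt = str(rng.choice([a for a in CANONICAL_AA if a != wt]))
            seq[pos - 1] = alt
            variants.append(SubstitutionVariant(int(pos), wt, alt))
        records.append(
            HomologRecord(
                id=rid, sequence="".join(seq), description=f"{rid} histone {reference.family}"
            )
        )
        truth[rid] = variants
    return records, truth


def ground_truth_labels(effects: dict[str, float], threshold: float) -> dict[str, str]:
    """Binary labels from latent shifts: repressor iff delta <= threshold."""
    if threshold >= 0:
        raise ValueError("threshold must be negative (repressors lower the signal)")
    return {c: ("repressor" if d <= threshold else "neutral") for c, d in effects.items()}


def write_simulation(
    table: ScreenCountTable, truth: pd.DataFrame, outdir: str
) -> None:
    """Write counts/sample-sheet/controls/ground-truth TSVs for the CLI."""
    import os

    os.makedirs(outdir, exist_ok=True)
    table.counts.to_csv(os.path.join(outdir, "counts.tsv"), sep="\t", index_label="construct")
    table.sample_meta.to_csv(os.path.join(outdir, "samples.tsv"), sep="\t", index_label="sample")
    with open(os.path.join(outdir, "controls.txt"), "w") as fh:
        fh.write("\n".join(table.control_ids) + "\n")
    truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index_label="construct")
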