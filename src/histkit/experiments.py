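"""End-to-end synthetic-screen benchmarks.

These routines wire the generator, the screen statistics and the classifier
into the reference experiments the package is validated on: training the
tail repression classifier on a simulated double-mutant sort-seq screen
(optionally with flipped training labels emulating a noisier readout),
measuring replicate concordance, and checking false-positive control on a
null screen.  All randomness derives from a single integer seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import DesignConfig, greedy_search
from .model import LabeledTailDataset, TrainConfig, evaluate, labels_from_screen, train
from .refs import H4_TAIL, H4_TAIL_REFERENCE
from .screen import (
    ScreenCountTable,
    call_hits,
    replicate_concordance,
    test_enrichment,
)
from .simulate import EffectModel, ScreenSimConfig, simulate_effects, simulate_screen_counts
from .variants import CANONICAL_AA, SubstitutionVariant, apply_variants, design_double_library


def _subseeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def sample_tail_singles(n: int, seed: int) -> list[SubstitutionVariant]:
    """Sample ``n`` distinct single substitutions within the 30-aa H4 tail."""
    pool = [
        SubstitutionVariant(pos, wt, alt)
        for pos, wt in enumerate(H4_TAIL, start=1)
        for alt in CANONICAL_AA
        if alt != wt
    ]
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


def simulate_double_mutant_screen(
    seed: int,
    n_singles: int = 189,
    n_pairs: int = 3694,
    model: EffectModel | None = None,
    config: ScreenSimConfig | None = None,
):
    """Simulate the combinatorial tail screen: counts, truth and sequences.

    Defaults mirror the combinatorial library scale (189 singles, 3694
    doubles) with 20% of singles as repressors at delta = -1.5, epistasis SD
    0.2, depth 1,000 reads/construct/bin, Gamma-Poisson phi = 0.05 and 2
    replicates.
    """
    s_pick, s_pairs, s_fx, s_screen = _subseeds(seed, 4)
    singles = sample_tail_singles(n_singles, s_pick)
    doubles = design_double_library(singles, n_pairs, s_pairs)
    single_ids = [str(v) for v in singles]
    pair_ids = [(str(a), str(b)) for a, b in doubles.pairs]
    model = model or EffectModel(pi=0.2, delta_repressor=-1.5, tau=0.2)
    effects = simulate_effects(single_ids, pair_ids, model, s_fx)
    config = config or ScreenSimConfig(depth=1000.0, phi=0.05, replicates=2, seed=s_screen)
    table, truth = simulate_screen_counts(effects, config)

    by_name = {str(v): v for v in singles}
    seq_map = {}
    for cid in effects:
        variants = {by_name[p] for p in cid.split("+")}
        seq_map[cid] = apply_variants(H4_TAIL_REFERENCE, variants)
    return table, truth, seq_map, effects


def flip_train_labels(
    dataset: LabeledTailDataset, fraction: float, seed: int
) -> LabeledTailDataset:
    """Flip a uniformly random fraction of training-split labels in place of
    a noisier experimental readout; test labels are untouched."""
    frame = dataset.frame.copy()
    train_idx = frame.index[frame["split"] == "train"].to_numpy()
    rng = np.random.default_rng(seed)
    k = int(round(fraction * len(train_idx)))
    chosen = rng.choice(train_idx, size=k, replace=False)
    frame.loc[chosen, "label"] = 1 - frame.loc[chosen, "label"]
    return LabeledTailDataset(frame=frame, wt_sequence=dataset.wt_sequence, length=dataset.length)


def double_mutant_benchmark(
    seed: int,
    flip_fraction: float = 0.0,
    n_singles: int = 189,
    n_pairs: int = 3694,
    epochs: int = 50,
    n_at: int = 100,
) -> dict[str, float]:
    """Train the classifier on a simulated double-mutant screen and evaluate.

    Labels come from the screen-statistics pipeline (padj < 0.05, depleted
    from the high-signal bin); the classifier trains with the default
    configuration and the fallback embedder; performance is precision@100
    over test prevalence on the held-out split.
    """
    s_split, s_flip, s_train = _subseeds(seed + 1_000_003, 3)
    table, truth, seq_map, effects = simulate_double_mutant_screen(seed)
    result = test_enrichment(table)
    dataset = labels_from_screen(result, seq_map, split_seed=s_split)
    if flip_fraction > 0:
        dataset = flip_train_labels(dataset, flip_fraction, s_flip)
    cfg = TrainConfig(epochs=epochs, seed=s_train)
    model = train(dataset, cfg, embedder_id="fallback")
    report = evaluate(model, dataset, n=n_at)
    return {
        "enrichment": report.enrichment,
        "precision_at_n": report.precision_at_n,
        "prevalence": report.prevalence,
        "auc": report.auc,
        "n_test": report.n_test,
        "n_constructs": len(seq_map),
    }


def null_screen_fraction(
    seed: int, n_constructs: int = 4600, depth: float = 1000.0,
    phi: float = 0.05, replicates: int = 2, alpha: float = 0.05,
) -> float:
    """Fraction of non-control constructs called significant on a null screen."""
    effects = {f"c{i:05d}": 0.0 for i in range(n_constructs)}
    config = ScreenSimConfig(depth=depth, phi=phi, replicates=replicates, seed=seed)
    table, _ = simulate_screen_counts(effects, config)
    result = test_enrichment(table)
    usable = result[~result["is_control"].astype(bool)]
    return float((usable["padj"] < alpha).mean())


def _replicate_subtable(table: ScreenCountTable, replicate: int) -> ScreenCountTable:
    cols = [
        s for s in table.counts.columns
        if table.sample_meta.loc[s, "replicate"] == replicate
    ]
    return ScreenCountTable(
        table.counts[cols], table.sample_meta.loc[cols], table.control_ids
    )


def concordance_experiment(
    seed: int, n_constructs: int = 2000, depth: float = 1000.0, phi: float = 0.05,
) -> float:
    """R^2 of per-replicate log2fc on a screen with a continuous effect spread.

    Per-construct latent shifts are Normal(0, 1); both replicates share the
    planted effects and library abundances, and each replicate's log2fc is
    computed independently (the known count overdispersion is supplied since
    a single replicate cannot estimate it).
    """
    s_fx, s_screen = _subseeds(seed + 7, 2)
    ids = [f"c{i:05d}" for i in range(n_constructs)]
    effects = simulate_effects(
        ids, [], EffectModel(continuous=True, sigma_delta=1.0), s_fx
    )
    config = ScreenSimConfig(depth=depth, phi=phi, replicates=2, seed=s_screen)
    table, _ = simulate_screen_counts(effects, config)
    res = [
        test_enrichment(_replicate_subtable(table, rep), dispersion=phi)
        for rep in (1, 2)
    ]
    return replicate_concordance(res[0], res[1]).r2


def repressor_recovery(
    seed: int, n_singles: int = 200, delta: float = -1.5, depth: float = 1000.0,
) -> tuple[float, float]:
    """(recall of true repressors, fraction of hits with the correct sign)."""
    s_fx, s_screen = _subseeds(seed + 13, 2)
    ids = [f"v{i:04d}" for i in range(n_singles)]
    effects = simulate_effects(
        ids, [], EffectModel(pi=0.2, delta_repressor=delta, tau=0.0), s_fx
    )
    config = ScreenSimConfig(depth=depth, phi=0.05, replicates=2, seed=s_screen)
    table, truth = simulate_screen_counts(effects, config)
    result = test_enrichment(table)
    hits = call_hits(result)
    true_rep = {c for c, d in effects.items() if d < 0}
    if not true_rep:
        return float("nan"), float("nan")
    recall = len(hits["depleted"] & true_rep) / len(true_rep)
    called = hits["depleted"] | hits["enriched"]
    if not called:
        return recall, float("nan")
    correct = sum(1 for c in called if (effects.get(c, 0.0) < 0) == (c in hits["depleted"]))
    return recall, correct / len(called)


def design_demo(model, max_mutations: int = 8):
    """Run the greedy search from the G4D anchor with default settings."""
    config = DesignConfig(max_mutations=max_mutations)
    return greedy_search(model, config)
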