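"""Closed feedback → reward → generation loop.

The remote de novo runner of a production setup is abstracted behind a
small generator contract: anything with a
``generate(reward_callable, n, seed) -> list[str]`` method.  The shipped
:class:`ToyGenerator` samples from a fixed molecule pool with probability
proportional to ``exp(reward / temperature)`` — a desk-scale stand-in that
still responds to reward shaping, so the loop's alignment behaviour is
testable end-to-end.

Each iteration: generate candidates → score them with the current reward
(feedback reward g plus the preference-model probability f when a model
exists) → select a diverse review subset → collect feedback from the
oracle (a simulated chemist or, in principle, a human) → update the
feedback table, size window and reward model → persist everything to an
iteration archive that can be reloaded to resume the run bit-identically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Protocol, Sequence

import numpy as np
import yaml

from .chem import ParsedMolecule, morgan_fingerprint, parse_molecule, tanimoto
from .feedback import (
    FeedbackRecord,
    FeedbackTable,
    derive_reward_inputs,
    load_feedback,
    save_feedback,
)
from .model import (
    ClassifierSpec,
    RewardModelState,
    build_training_set,
    load_model,
    predict_preference,
    save_model,
    train_reward_model,
)
from .reward import RewardConfig, RewardInputs, SizeWindow, compute_reward, total_score

#: Oracle contract: (molecule, molecule_id, iteration, seed) -> FeedbackRecord
FeedbackOracle = Callable[[ParsedMolecule, str, int, int], FeedbackRecord]


class GeneratorContract(Protocol):
    """What the loop requires of a molecule generator."""

    def generate(
        self, reward_callable: Callable[[str], float], n: int, seed: int
    ) -> list[str]: ...

    def state(self) -> dict: ...


class LoopError(RuntimeError):
    """The loop cannot proceed (e.g. the generator produced nothing usable)."""


def iteration_seed(base_seed: int, iteration: int) -> int:
    """Stateless per-iteration seed so resumed runs reproduce exactly."""
    return int(np.random.SeedSequence([base_seed, iteration]).generate_state(1)[0] % 2**31)


class ToyGenerator:
    """Reward-proportional sampler over a fixed SMILES pool.

    Samples *n* molecules without replacement with probability proportional
    to ``exp(reward / temperature)``; as temperature → 0 this approaches
    picking the top-*n* by reward (ties by pool order).
    """

    def __init__(self, pool: Sequence[str], temperature: float = 0.1) -> None:
        if not pool:
            raise ValueError("pool must be non-empty")
        if temperature <= 0:
            raise ValueError("temperature must be > 0")
        self.pool = list(pool)
        self.temperature = temperature

    def generate(
        self, reward_callable: Callable[[str], float], n: int, seed: int
    ) -> list[str]:
        if n >= len(self.pool):
            if n > len(self.pool):
                warnings.warn(
                    f"requested {n} molecules from a pool of {len(self.pool)};"
                    " returning the whole pool",
                    stacklevel=2,
                )
            return list(self.pool)
        rewards = np.array([reward_callable(s) for s in self.pool], dtype=float)
        # Gumbel-top-k: adding Gumbel noise to the logits and taking the top
        # n is exactly sampling without replacement with probability
        # proportional to exp(reward / temperature), and stays numerically
        # stable as temperature -> 0 (where it degenerates to argmax).
        rng = np.random.default_rng(seed)
        keys = rewards / self.temperature + rng.gumbel(size=len(self.pool))
        idx = np.argsort(-keys, kind="stable")[:n]
        return [self.pool[i] for i in sorted(idx)]

    def state(self) -> dict:
        return {"type": "toy", "temperature": self.temperature, "pool": self.pool}


def select_for_review(
    candidates: Sequence[str],
    k: int,
    strategy: str = "maxmin",
    seed: int = 0,
) -> list[str]:
    """Choose *k* unique molecules for chemist review.

    ``random`` takes a seeded uniform subset; ``maxmin`` greedily maximizes
    the minimum Tanimoto distance to the already-picked molecules, starting
    from a seeded random pick — the standard diversity selection.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    unique = list(dict.fromkeys(candidates))
    if k >= len(unique):
        return unique
    rng = np.random.default_rng(seed)
    if strategy == "random":
        idx = sorted(rng.choice(len(unique), size=k, replace=False))
        return [unique[i] for i in idx]
    if strategy != "maxmin":
        raise ValueError(f"unknown selection strategy: {strategy!r}")
    fps = [morgan_fingerprint(parse_molecule(s)) for s in unique]
    picked = [int(rng.integers(len(unique)))]
    min_dist = np.array([1.0 - tanimoto(fps[picked[0]], fp) for fp in fps])
    min_dist[picked[0]] = -1.0
    while len(picked) < k:
        nxt = int(np.argmax(min_dist))
        picked.append(nxt)
        for i, fp in enumerate(fps):
            d = 1.0 - tanimoto(fps[nxt], fp)
            if d < min_dist[i]:
                min_dist[i] = d
        min_dist[nxt] = -1.0
    return [unique[i] for i in sorted(picked)]


def make_reward_callable(
    inputs: RewardInputs,
    config: RewardConfig = RewardConfig(),
    model: RewardModelState | None = None,
) -> Callable[[str], float]:
    """Total score S = f + g; f is the model's liked-probability when fitted, else 0."""
    cache: dict[str, float] = {}

    def score(smiles: str) -> float:
        if smiles in cache:
            return cache[smiles]
        pmol = parse_molecule(smiles)
        breakdown = compute_reward(pmol, inputs, config)
        f = (
            predict_preference(model, pmol)
            if model is not None and model.fitted
            else 0.0
        )
        s = total_score(f, breakdown)
        cache[smiles] = s
        return s

    return score


@dataclass(frozen=True)
class IterationArchive:
    """Pointer to one persisted iteration directory."""

    index: int
    path: Path


@dataclass
class LoopState:
    """In-memory loop state between iterations (reloadable from an archive)."""

    table: FeedbackTable
    model: RewardModelState | None = None
    next_iteration: int = 0


def _persist_iteration(
    directory: Path,
    batch: Sequence[str],
    scores: Sequence[float],
    selected: Sequence[str],
    table: FeedbackTable,
    model: RewardModelState | None,
    generator: GeneratorContract,
    snapshot: dict,
) -> None:
    import pandas as pd

    directory.mkdir(parents=True, exist_ok=True)
    selected_set = set(selected)
    pd.DataFrame(
        {
            "id": [f"gen_{i}" for i in range(len(batch))],
            "smiles": list(batch),
            "score": [round(s, 10) for s in scores],
            "selected": [int(s in selected_set) for s in batch],
        }
    ).to_csv(directory / "molecules.csv", index=False, lineterminator="\n")
    save_feedback(table, directory)
    if model is not None:
        save_model(model, directory)
    (directory / "generator_state.json").write_text(
        json.dumps(generator.state(), indent=1) + "\n", encoding="utf-8"
    )
    (directory / "config_snapshot.yaml").write_text(
        yaml.safe_dump(snapshot, sort_keys=True), encoding="utf-8"
    )


def load_archive(
    directory: str | Path,
    initial_window: SizeWindow | None = None,
) -> LoopState:
    """Reload an iteration archive into an equivalent in-memory state."""
    directory = Path(directory)
    snapshot = yaml.safe_load((directory / "config_snapshot.yaml").read_text())
    window = initial_window
    if window is None and "initial_window" in snapshot:
        window = SizeWindow(**snapshot["initial_window"])
    table = load_feedback(directory, size_window=window)
    model = None
    if (directory / "manifest.json").exists():
        model = load_model(directory)
    return LoopState(table=table, model=model, next_iteration=snapshot["iteration"] + 1)


def run_loop(
    generator: GeneratorContract,
    oracle: FeedbackOracle,
    run_dir: str | Path,
    n_iterations: int,
    seed: int,
    *,
    k: int = 10,
    strategy: str = "maxmin",
    n_generate: int = 30,
    reward_config: RewardConfig = RewardConfig(),
    initial_window: SizeWindow = SizeWindow(),
    classifier_spec: ClassifierSpec = ClassifierSpec(),
    use_model: bool = True,
    feedback_weight: float = 1.0,
    prior_rows: Sequence[tuple[str, int]] | None = None,
    global_properties: Sequence[str] = ("size",),
    state: LoopState | None = None,
) -> list[IterationArchive]:
    """Run the closed feedback loop and persist one archive per iteration.

    *n_iterations* is the total number of iterations for the run; passing a
    *state* reloaded from an earlier archive resumes after it and, with the
    same *seed*, reproduces the continuation exactly.
    """
    if n_iterations < 0:
        raise ValueError("n_iterations must be >= 0")
    run_dir = Path(run_dir)
    if state is None:
        state = LoopState(
            table=FeedbackTable(
                global_properties=global_properties, size_window=initial_window
            )
        )
    archives: list[IterationArchive] = []

    for t in range(state.next_iteration, n_iterations):
        seed_t = iteration_seed(seed, t)
        inputs = derive_reward_inputs(
            state.table, radius=classifier_spec.radius, n_bits=classifier_spec.n_bits
        )
        reward = make_reward_callable(
            inputs, reward_config, state.model if use_model else None
        )
        batch = generator.generate(reward, n_generate, seed_t)
        batch = [s for s in batch if _parses(s)]
        if not batch:
            raise LoopError(f"iteration {t}: generator produced no parseable molecules")
        scores = [reward(s) for s in batch]
        selected = select_for_review(batch, k, strategy, seed_t)

        for j, smiles in enumerate(selected):
            pmol = parse_molecule(smiles)
            record = oracle(pmol, f"it{t}_m{j}", t, seed_t + j)
            state.table.add(record)

        rows = build_training_set(
            state.table,
            prior_rows=prior_rows,
            feedback_weight=feedback_weight,
            sort_of_weight=reward_config.sort_of_weight,
            radius=classifier_spec.radius,
            n_bits=classifier_spec.n_bits,
        )
        if use_model and {r.label for r in rows} == {0, 1}:
            state.model = train_reward_model(rows, classifier_spec, seed=seed_t)

        directory = run_dir / f"iter_{t}"
        snapshot = {
            "iteration": t,
            "seed": seed,
            "k": k,
            "strategy": strategy,
            "n_generate": n_generate,
            "use_model": use_model,
            "feedback_weight": feedback_weight,
            "global_properties": list(global_properties),
            "reward_config": {
                "similarity_cutoff": reward_config.similarity_cutoff,
                "sort_of_weight": reward_config.sort_of_weight,
                "prefactor": reward_config.prefactor,
                "count_cap": reward_config.count_cap,
            },
            "initial_window": {
                "low_center": initial_window.low_center,
                "high_center": initial_window.high_center,
                "low_slope": initial_window.low_slope,
                "high_slope": initial_window.high_slope,
                "alpha": initial_window.alpha,
            },
        }
        _persist_iteration(
            directory, batch, scores, selected, state.table, state.model, generator, snapshot
        )
        archives.append(IterationArchive(index=t, path=directory))
        state.next_iteration = t + 1

    return archives


def _parses(smiles: str) -> bool:
    try:
        parse_molecule(smiles)
        return True
    except ValueError:
        return False


def read_batch(archive: IterationArchive) -> list[tuple[str, float]]:
    """(smiles, score) rows of the generated batch stored in an archive."""
    import pandas as pd

    frame = pd.read_csv(archive.path / "molecules.csv")
    return list(zip(frame["smiles"], frame["score"]))


def archive_mean_scores(archives: Sequence[IterationArchive]) -> list[float]:
    """Per-iteration mean of the scores assigned at generation time.

    This is the loop's learning curve: the total score S = f + g under the
    reward state current when each batch was generated.
    """
    return [
        float(np.mean([score for _, score in read_batch(a)])) for a in archives
    ]


def batch_mean_rewards(
    archives: Sequence[IterationArchive],
    inputs: RewardInputs,
    config: RewardConfig = RewardConfig(),
) -> list[float]:
    """Mean feedback reward g of each archived batch under fixed inputs.

    Evaluating every batch under the same (typically final) reference sets
    makes batches comparable across iterations, which per-iteration scores
    are not (the reward itself moves as feedback accumulates).
    """
    means = []
    for archive in archives:
        gs = [
            compute_reward(parse_molecule(smiles), inputs, config).g
            for smiles, _ in read_batch(archive)
        ]
        means.append(float(np.mean(gs)))
    return means
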