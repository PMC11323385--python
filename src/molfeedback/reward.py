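"""Feedback-derived reward function g(x) and the total score S(x) = f(x) + g(x).

The reward combines six equally weighted components derived from chemist
feedback:

* ``γ+`` / ``γ−`` — presence of liked / disliked substructure patterns,
  counted per pattern (capped, default cap 1, so a single liability cannot
  dominate);
* ``δ+`` / ``δ−`` / ``δ±`` — maximum ECFP4 Tanimoto similarity to the liked,
  disliked and sort-of-liked reference molecules, gated by a cutoff: a
  similarity not exceeding 0.5 contributes exactly 0;
* ``φ(MS)`` — a double-sigmoid desirability of the molecular size (heavy-atom
  count), whose window adapts as size feedback arrives.

With the default configuration g = (1/6)(γ+ − γ− + δ+ − δ− + 0.5·δ± + φ)
and is bounded in [−1/3, 7/12].  g is added to the project's own scoring
function f(x): S(x) = f(x) + g(x); S may therefore exceed 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

from scipy.special import expit

from .chem import Fingerprint, ParsedMolecule, count_liability_matches, tanimoto

#: Minimum allowed gap (heavy atoms) between the two size-window centers.
MIN_WINDOW_GAP = 2.0


@dataclass(frozen=True)
class SizeWindow:
    """Adaptive acceptable-size range scored by a double sigmoid.

    ``low_center``/``high_center`` are the half-height points (heavy atoms)
    of the rising and falling logistics; ``alpha`` is the fraction by which
    a center moves toward an observed size when the chemist gives size
    feedback.  The defaults cover a deliberately wide range so that early
    iterations are not size-constrained.
    """

    low_center: float = 10.0
    high_center: float = 60.0
    low_slope: float = 1.0
    high_slope: float = 1.0
    alpha: float = 0.25

    def __post_init__(self) -> None:
        if not self.low_center < self.high_center:
            raise ValueError("size window requires low_center < high_center")
        if self.low_slope <= 0 or self.high_slope <= 0:
            raise ValueError("size window slopes must be positive")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")


@dataclass(frozen=True)
class RewardConfig:
    """Constants of g(x)."""

    similarity_cutoff: float = 0.5
    sort_of_weight: float = 0.5
    prefactor: float = 1.0 / 6.0
    count_cap: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.similarity_cutoff < 1:
            raise ValueError("similarity_cutoff must lie in [0, 1)")
        if self.count_cap < 1:
            raise ValueError("count_cap must be >= 1")
        for name in ("sort_of_weight", "prefactor"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class RewardInputs:
    """Reference sets extracted from the feedback table.

    SMARTS lists are deduplicated; fingerprint collections are sets, so
    duplicate molecules in a rating class collapse to one reference.
    """

    liked_fps: frozenset[Fingerprint] = frozenset()
    disliked_fps: frozenset[Fingerprint] = frozenset()
    sort_of_fps: frozenset[Fingerprint] = frozenset()
    liked_smarts: tuple[str, ...] = ()
    disliked_smarts: tuple[str, ...] = ()
    size_window: SizeWindow = SizeWindow()


@dataclass(frozen=True)
class RewardBreakdown:
    """The six components of g(x) plus their weighted combination."""

    gamma_plus: float
    gamma_minus: float
    delta_plus: float
    delta_minus: float
    delta_pm: float
    size_score: float
    g: float


def gamma(mol: ParsedMolecule, smarts_list: Iterable[str], count_cap: int = 1) -> float:
    """Capped, normalized count of distinct matching patterns: min(count, cap)/cap."""
    if count_cap < 1:
        raise ValueError("count_cap must be >= 1")
    return min(count_liability_matches(mol, smarts_list), count_cap) / count_cap


def delta(
    query_fp: Fingerprint,
    ref_fps: Iterable[Fingerprint],
    cutoff: float = 0.5,
) -> float:
    """Cutoff-gated nearest-reference Tanimoto similarity.

    Returns the maximum similarity of *query_fp* to the reference set if it
    is strictly greater than *cutoff*, else 0.0 (and 0.0 for an empty set).
    """
    if not 0 <= cutoff < 1:
        raise ValueError("cutoff must lie in [0, 1)")
    best = 0.0
    found = False
    for ref in ref_fps:
        found = True
        s = tanimoto(query_fp, ref)
        if s > best:
            best = s
    if not found:
        return 0.0
    return best if best > cutoff else 0.0


def size_score(n_heavy: int, window: SizeWindow) -> float:
    """Double-sigmoid size desirability φ(n) ∈ (0, 1).

    φ(n) = σ(low_slope·(n − low_center)) · σ(high_slope·(high_center − n))
    with σ the standard logistic: ≈1 inside the window, →0 far outside.
    """
    if n_heavy < 0:
        raise ValueError("heavy-atom count must be >= 0")
    rise = float(expit(window.low_slope * (n_heavy - window.low_center)))
    fall = float(expit(window.high_slope * (window.high_center - n_heavy)))
    return rise * fall


def update_size_window(
    window: SizeWindow, observed_n: int, verdict: str
) -> SizeWindow:
    """Move one window center toward an observed size, per chemist verdict.

    ``too_large`` pulls ``high_center`` toward *observed_n* by fraction
    ``alpha`` of the gap; ``too_small`` does the same for ``low_center``.
    ``ok`` leaves an in-window size alone but relaxes the violated bound
    when the accepted molecule lies outside the window.  Updates are clipped
    so the centers keep a gap of at least :data:`MIN_WINDOW_GAP`.
    """
    if observed_n < 1:
        raise ValueError("observed_n must be >= 1")
    if verdict not in ("too_small", "too_large", "ok"):
        raise ValueError(f"unknown size verdict: {verdict!r}")

    if verdict == "ok":
        if observed_n > window.high_center:
            verdict = "too_large"  # relax upper bound outward
        elif observed_n < window.low_center:
            verdict = "too_small"
        else:
            return window

    a = window.alpha
    if verdict == "too_large":
        new_high = window.high_center + a * (observed_n - window.high_center)
        new_high = max(new_high, window.low_center + MIN_WINDOW_GAP)
        return replace(window, high_center=new_high)
    new_low = window.low_center + a * (observed_n - window.low_center)
    new_low = min(new_low, window.high_center - MIN_WINDOW_GAP)
    return replace(window, low_center=new_low)


def compute_reward(
    mol: ParsedMolecule,
    inputs: RewardInputs,
    config: RewardConfig = RewardConfig(),
    query_fp: Fingerprint | None = None,
) -> RewardBreakdown:
    """Evaluate all six components of g(x) for one molecule.

    *query_fp* may be supplied to reuse a precomputed fingerprint; it must
    then share parameters with the reference fingerprints.
    """
    from .chem import morgan_fingerprint

    if query_fp is None:
        ref = next(
            iter(inputs.liked_fps or inputs.disliked_fps or inputs.sort_of_fps),
            None,
        )
        radius = ref.radius if ref is not None else 2
        n_bits = ref.n_bits if ref is not None else 2048
        query_fp = morgan_fingerprint(mol, radius=radius, n_bits=n_bits)

    gp = gamma(mol, inputs.liked_smarts, config.count_cap)
    gm = gamma(mol, inputs.disliked_smarts, config.count_cap)
    dp = delta(query_fp, inputs.liked_fps, config.similarity_cutoff)
    dm = delta(query_fp, inputs.disliked_fps, config.similarity_cutoff)
    dpm = delta(query_fp, inputs.sort_of_fps, config.similarity_cutoff)
    phi = size_score(mol.heavy_atom_count, inputs.size_window)
    g = config.prefactor * (gp - gm + dp - dm + config.sort_of_weight * dpm + phi)
    return RewardBreakdown(
        gamma_plus=gp,
        gamma_minus=gm,
        delta_plus=dp,
        delta_minus=dm,
        delta_pm=dpm,
        size_score=phi,
        g=g,
    )


def total_score(f: float, breakdown: RewardBreakdown) -> float:
    """S(x) = f(x) + g(x): feedback reward added to the project scoring function."""
    if not math.isfinite(f):
        raise ValueError("f must be finite")
    return f + breakdown.g
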