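"""Stimulus/trial/spelling structure of the AMUSE auditory ERP paradigm.

One trial presents each of K=6 tones J=15 times in pseudo-randomized order
(90 presentations, SOA 175 ms, 15.75 s of stimulation) and yields a
one-out-of-six selection.  Two consecutive trials address one of 36 symbols
arranged in six groups of six: the first selection picks a group, the second
picks a symbol within that group.

Stimulus identifiers are 1-based (1..K).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "StimulusSequence",
    "Trial",
    "SymbolGrid",
    "DEFAULT_GRID",
    "generate_sequence",
    "label_function",
    "trial_duration",
    "decode_symbol",
    "TARGET",
    "NONTARGET",
]

#: class labels returned by :func:`label_function`
TARGET = "target"
NONTARGET = "nontarget"

#: paradigm defaults
K_STIMULI = 6
J_ITERATIONS = 15
SOA_S = 0.175
STIMULUS_DURATION_S = 0.040


@dataclass(frozen=True)
class StimulusSequence:
    """Ordered stimulus presentations of one trial.

    ``presentations`` holds K*J identifiers in 1..K; within each consecutive
    block of K presentations every stimulus appears exactly once.
    """

    trial_index: int
    presentations: np.ndarray  # shape (K*J,), int, values 1..K
    n_stimuli: int = K_STIMULI
    n_iterations: int = J_ITERATIONS
    soa: float = SOA_S
    stimulus_duration: float = STIMULUS_DURATION_S

    def __post_init__(self):
        pres = np.asarray(self.presentations, dtype=int)
        object.__setattr__(self, "presentations", pres)
        if pres.shape != (self.n_stimuli * self.n_iterations,):
            raise ValueError(
                f"expected {self.n_stimuli * self.n_iterations} presentations, "
                f"got {pres.shape}"
            )
        counts = np.bincount(pres, minlength=self.n_stimuli + 1)[1:]
        if not np.all(counts == self.n_iterations):
            raise ValueError("each stimulus must appear exactly J times")
        blocks = pres.reshape(self.n_iterations, self.n_stimuli)
        if not np.all(np.sort(blocks, axis=1) == np.arange(1, self.n_stimuli + 1)):
            raise ValueError(
                "each consecutive block of K presentations must contain every "
                "stimulus exactly once"
            )

    def __len__(self) -> int:
        return self.presentations.size


@dataclass(frozen=True)
class Trial:
    """A stimulus sequence plus the (possibly unknown) attended stimulus."""

    sequence: StimulusSequence
    attended: Optional[int] = None

    def __post_init__(self):
        if self.attended is not None and not (
            1 <= self.attended <= self.sequence.n_stimuli
        ):
            raise ValueError(
                f"attended stimulus {self.attended} outside 1..{self.sequence.n_stimuli}"
            )

    def labels(self) -> list[str]:
        """Target/non-target label of every presentation (requires ground truth)."""
        if self.attended is None:
            raise ValueError("attended stimulus unknown")
        return [
            label_function(self.attended, int(p)) for p in self.sequence.presentations
        ]


# 36 spellable symbols: 26 letters, three German umlauts, underscore for white
# space and six punctuation marks, in six groups of six.  Any 6x6 grouping is
# accepted by SymbolGrid; this layout is the package default.
_DEFAULT_SYMBOLS = [
    ["A", "B", "C", "D", "E", "F"],
    ["G", "H", "I", "J", "K", "L"],
    ["M", "N", "O", "P", "Q", "R"],
    ["S", "T", "U", "V", "W", "X"],
    ["Y", "Z", "Ä", "Ö", "Ü", "_"],
    [".", ",", "!", "?", ":", "-"],
]


@dataclass(frozen=True)
class SymbolGrid:
    """Six ordered groups of six symbols; 36 distinct symbols in total."""

    groups: tuple = tuple(tuple(g) for g in _DEFAULT_SYMBOLS)

    def __post_init__(self):
        groups = tuple(tuple(g) for g in self.groups)
        object.__setattr__(self, "groups", groups)
        if len(groups) != 6 or any(len(g) != 6 for g in groups):
            raise ValueError("symbol grid must be 6 groups of 6 symbols")
        flat = [s for g in groups for s in g]
        if len(set(flat)) != 36:
            raise ValueError("symbol grid must contain 36 distinct symbols")

    @property
    def symbols(self) -> list[str]:
        return [s for g in self.groups for s in g]

    def locate(self, symbol: str) -> tuple[int, int]:
        """Return the 1-based (group, within-group) selections spelling *symbol*."""
        for gi, group in enumerate(self.groups, start=1):
            if symbol in group:
                return gi, group.index(symbol) + 1
        raise KeyError(f"symbol {symbol!r} not in grid")


DEFAULT_GRID = SymbolGrid()


def generate_sequence(
    K: int = K_STIMULI,
    J: int = J_ITERATIONS,
    seed: int | np.random.Generator = 0,
    *,
    trial_index: int = 0,
    soa: float = SOA_S,
    stimulus_duration: float = STIMULUS_DURATION_S,
    block_constraint: Optional[Callable[[np.ndarray, np.ndarray], bool]] = None,
) -> StimulusSequence:
    """Generate a pseudo-randomized stimulus sequence of J iteration blocks.

    Each iteration block is an independent uniform permutation of 1..K.
    ``block_constraint(previous_block, candidate_block)`` is an optional hook:
    candidate blocks are redrawn until it returns True (e.g. to forbid an
    immediate stimulus repeat at block seams); by default no constraint is
    imposed.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if J < 1:
        raise ValueError("J must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    blocks: list[np.ndarray] = []
    for _ in range(J):
        block = rng.permutation(K) + 1
        if block_constraint is not None and blocks:
            while not block_constraint(blocks[-1], block):
                block = rng.permutation(K) + 1
        blocks.append(block)
    return StimulusSequence(
        trial_index=trial_index,
        presentations=np.concatenate(blocks),
        n_stimuli=K,
        n_iterations=J,
        soa=soa,
        stimulus_duration=stimulus_duration,
    )


def label_function(attended: int, presented: int) -> str:
    """Binary class of a presentation: target iff the attended stimulus is shown.

    This is the paradigm constraint that makes unsupervised decoding tractable:
    fixing the attended stimulus fixes the label of all 90 presentations.
    """
    if attended < 1 or presented < 1:
        raise ValueError("stimulus identifiers are 1-based")
    return TARGET if presented == attended else NONTARGET


def trial_duration(sequence: StimulusSequence) -> float:
    """Duration in seconds of the stimulation sequence (presentations x SOA)."""
    return len(sequence) * sequence.soa


def decode_symbol(
    first_selection: int, second_selection: int, grid: SymbolGrid = DEFAULT_GRID
) -> str:
    """Map a two-step (group, within-group) selection to its symbol.

    A spelled symbol is correct iff both one-out-of-six selections are correct.
    """
    if not isinstance(grid, SymbolGrid):
        raise TypeError("grid must be a SymbolGrid")
    if not (1 <= first_selection <= 6 and 1 <= second_selection <= 6):
        raise ValueError("selections must be in 1..6")
    return grid.groups[first_selection - 1][second_selection - 1]
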