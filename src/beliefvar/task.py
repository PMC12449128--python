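"""Marble-task session generation.

A session presents a set of jars, each holding an unknown proportion of blue
marbles. On every trial the subject watches five successive samples drawn
(with replacement) from one jar, then reports an estimate of its blue-marble
proportion. Samples contain 1, 5 or 9 marbles, manipulating informativeness.
Each jar's five samples are drawn once, so every repetition of a jar replays
the same sample set in a freshly permuted order; each jar appears exactly
once per block (one scanner run per block).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .observer import SampleDraw

__all__ = [
    "Jar",
    "Trial",
    "TrialSequence",
    "make_jars",
    "draw_jar_samples",
    "build_session",
    "session_table",
    "write_session_tsv",
    "read_session_tsv",
    "block_events",
]

DEFAULT_SIZES = (1, 5, 9)
SAMPLE_DURATION_S = 1.0
#: inter-stimulus fixation range (uniform on a 0.5 s grid)
ITI_RANGE_S = (2.0, 6.0)
#: simulated estimation-phase response time range (true task allowed up to 7 s)
ESTIMATION_RT_RANGE_S = (2.0, 5.0)
GAMBLE_DURATION_S = 2.0
TRIAL_GAP_S = 2.0


@dataclass(frozen=True)
class Jar:
    jar_id: int
    p_blue: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_blue < 1.0):
            raise ValueError("p_blue must lie strictly inside (0, 1)")


@dataclass
class Trial:
    trial_id: int
    block_id: int
    jar_id: int
    p_blue: float
    samples: list          # five SampleDraw, in presentation order
    sample_onsets_s: list  # onset of each sample, seconds from run start
    estimation_onset_s: float
    estimation_duration_s: float
    gamble_onset_s: float
    gamble_duration_s: float


@dataclass
class TrialSequence:
    """An ordered session of trials plus the seed that generated it."""

    trials: list
    jars: list
    rng_seed: int
    n_blocks: int

    def block(self, block_id: int) -> list:
        return [t for t in self.trials if t.block_id == block_id]

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def make_jars(n_jars: int, p_min: float = 0.1, p_max: float = 0.91) -> list[Jar]:
    """Evenly spaced jar proportions spanning [p_min, p_max]."""
    if n_jars < 2:
        raise ValueError("need at least two jars")
    if not (0.0 < p_min < p_max < 1.0):
        raise ValueError("require 0 < p_min < p_max < 1")
    grid = np.linspace(p_min, p_max, n_jars)
    return [Jar(i, float(p)) for i, p in enumerate(grid)]


def draw_jar_samples(jar: Jar, sizes, rng: np.random.Generator) -> list[SampleDraw]:
    """Draw one fixed sample set for a jar, binomially at its p_blue."""
    out = []
    for size in sizes:
        n_blue = int(rng.binomial(int(size), jar.p_blue))
        out.append(SampleDraw(n_blue, int(size) - n_blue))
    return out


def _draw_iti(rng: np.random.Generator, iti_range_s=ITI_RANGE_S) -> float:
    lo, hi = iti_range_s
    steps = int(round((hi - lo) / 0.5))
    return lo + 0.5 * int(rng.integers(0, steps + 1))


def build_session(
    jars: list[Jar],
    n_blocks: int = 3,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    sizes=DEFAULT_SIZES,
    n_samples: int = 5,
    include_gamble: bool = True,
    iti_range_s=ITI_RANGE_S,
) -> TrialSequence:
    """Build a full session: per-jar sample sets, block orders, and timing.

    Every jar contributes one trial per block; jar order is randomized
    within block and the jar's fixed sample set is re-permuted per trial.
    Onsets are seconds from the start of the block's scanner run.
    """
    if not jars:
        raise ValueError("jars must be non-empty")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
        rng_seed = -1 if seed is None else int(seed)
    else:
        rng_seed = -1

    jar_samples = {
        jar.jar_id: draw_jar_samples(
            jar, rng.choice(list(sizes), size=n_samples), rng
        )
        for jar in jars
    }
    jar_by_id = {jar.jar_id: jar for jar in jars}

    trials: list[Trial] = []
    trial_id = 0
    for block_id in range(n_blocks):
        order = rng.permutation([jar.jar_id for jar in jars])
        t = 0.0
        for jar_id in order:
            perm = rng.permutation(n_samples)
            samples = [jar_samples[jar_id][k] for k in perm]
            onsets = []
            for _ in range(n_samples):
                onsets.append(t)
                t += SAMPLE_DURATION_S + _draw_iti(rng, iti_range_s)
            est_onset = t
            est_dur = float(rng.uniform(*ESTIMATION_RT_RANGE_S))
            t = est_onset + est_dur + 1.0
            if include_gamble:
                gamble_onset = t
                t += GAMBLE_DURATION_S
            else:
                gamble_onset = np.nan
            t += TRIAL_GAP_S
            trials.append(
                Trial(
                    trial_id=trial_id,
                    block_id=block_id,
                    jar_id=int(jar_id),
                    p_blue=jar_by_id[int(jar_id)].p_blue,
                    samples=samples,
                    sample_onsets_s=onsets,
                    estimation_onset_s=est_onset,
                    estimation_duration_s=est_dur,
                    gamble_onset_s=gamble_onset,
                    gamble_duration_s=GAMBLE_DURATION_S if include_gamble else np.nan,
                )
            )
            trial_id += 1
    return TrialSequence(trials=trials, jars=list(jars), rng_seed=rng_seed, n_blocks=n_blocks)


def session_table(seq: TrialSequence) -> pd.DataFrame:
    """Long-format session table: one row per (trial, sample)."""
    rows = []
    for t in seq.trials:
        for k, (draw, onset) in enumerate(zip(t.samples, t.sample_onsets_s)):
            rows.append(
                {
                    "trial_id": t.trial_id,
                    "block_id": t.block_id,
                    "jar_id": t.jar_id,
                    "p_blue": t.p_blue,
                    "sample_index": k + 1,
                    "n_blue": draw.n_blue,
                    "n_red": draw.n_red,
                    "onset_s": onset,
                    "duration_s": SAMPLE_DURATION_S,
                }
            )
    return pd.DataFrame(rows)


def write_session_tsv(seq: TrialSequence, path) -> None:
    session_table(seq).to_csv(path, sep="\t", index=False)


def read_session_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def block_events(seq: TrialSequence, block_id: int) -> pd.DataFrame:
    """BIDS-style events for one block: onset, duration, trial_type, trial_id.

    Sample events are tagged sample_1 ... sample_5 by within-trial position;
    estimation and gambling phases are separate event types.
    """
    rows = []
    for t in seq.block(block_id):
        for k, onset in enumerate(t.sample_onsets_s):
            rows.append(
                {
                    "onset": onset,
                    "duration": SAMPLE_DURATION_S,
                    "trial_type": f"sample_{k + 1}",
                    "trial_id": t.trial_id,
                }
            )
        rows.append(
            {
                "onset": t.estimation_onset_s,
                "duration": t.estimation_duration_s,
                "trial_type": "estimation",
                "trial_id": t.trial_id,
            }
        )
        if not np.isnan(t.gamble_onset_s):
            rows.append(
                {
                    "onset": t.gamble_onset_s,
                    "duration": t.gamble_duration_s,
                    "trial_type": "gamble",
                    "trial_id": t.trial_id,
                }
            )
    df = pd.DataFrame(rows).sort_values("onset", kind="stable").reset_index(drop=True)
    return df
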