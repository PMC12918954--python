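"""Up-down von Frey threshold estimation and latency cutoffs.

The 50% paw-withdrawal threshold (PWT) is estimated with the Dixon
up-down staircase: filaments of log-spaced bending force are presented
starting mid-set, moving one step down after a withdrawal and one step
up after none, continuing for four trials past the first response
reversal.  The estimate is ``10**(Xf + k * delta)`` grams, where ``Xf``
is the log10 force of the final filament, ``delta`` the mean log10
spacing of the set, and ``k`` a coefficient determined by the terminal
response pattern.  The coefficient table shipped with the package is
derived from the staircase's underlying statistical model — the maximum
likelihood threshold of the response sequence under a cumulative-normal
psychometric function whose spread equals one filament step — which is
the definition the classical tabulated values approximate.  Sessions
with no withdrawal at the stiffest filament return the ceiling force;
sessions withdrawing down to the weakest return the floor force.

A seeded logistic responder simulates sessions for calibration and
consistency testing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.stats import norm

__all__ = [
    "FilamentSet",
    "UpDownSession",
    "simulate_updown_session",
    "pwt_updown",
    "latency_with_cutoff",
    "compute_k_table",
    "SessionError",
]

# Stoelting von Frey kit, 0.02-1.4 g (forces in grams)
DEFAULT_FORCES = (0.02, 0.04, 0.07, 0.16, 0.4, 0.6, 1.0, 1.4)

WITHDRAW = "X"
NO_WITHDRAW = "O"

MAX_TRIALS = 30
POST_REVERSAL_TRIALS = 4


class SessionError(ValueError):
    """Raised for malformed up-down sessions."""


@dataclass(frozen=True)
class FilamentSet:
    """An ordered set of von Frey filaments (forces in grams)."""

    forces: tuple[float, ...] = DEFAULT_FORCES

    def __post_init__(self) -> None:
        if len(self.forces) < 4:
            raise ValueError("at least 4 filaments required")
        if any(f <= 0 for f in self.forces):
            raise ValueError("forces must be positive")
        if any(b <= a for a, b in zip(self.forces, self.forces[1:])):
            raise ValueError("forces must be strictly increasing")

    @property
    def log_forces(self) -> np.ndarray:
        return np.log10(np.asarray(self.forces))

    @property
    def delta(self) -> float:
        """Mean log10 spacing between adjacent filaments."""
        return float(np.mean(np.diff(self.log_forces)))


@dataclass
class UpDownSession:
    """Ordered (filament index, withdrew?) trials of one staircase run."""

    trials: list[tuple[int, bool]]

    def responses(self) -> str:
        return "".join(WITHDRAW if r else NO_WITHDRAW for _, r in self.trials)

    def validate(self, filaments: FilamentSet) -> None:
        """Check the up-down rule: down after withdrawal, up after none,
        clamped at the set bounds."""
        n = len(filaments.forces)
        if not self.trials:
            raise SessionError("empty session")
        for (i, r), (j, _) in zip(self.trials, self.trials[1:]):
            expect = max(0, i - 1) if r else min(n - 1, i + 1)
            if j != expect:
                raise SessionError(
                    f"up-down rule violated: filament {i} with "
                    f"{'withdrawal' if r else 'no withdrawal'} must be followed "
                    f"by {expect}, got {j}"
                )
        if any(not 0 <= i < n for i, _ in self.trials):
            raise SessionError("filament index outside the set")


def simulate_updown_session(
    true_threshold_g: float,
    slope: float,
    filaments: FilamentSet | None = None,
    start_index: int | None = None,
    seed: int = 0,
) -> UpDownSession:
    """Simulate a staircase run with a logistic psychometric responder.

    Withdrawal probability is ``1 / (1 + exp(-slope * (log10 f - log10
    threshold)))`` (``slope`` per log10 unit; ``math.inf`` gives a
    deterministic step responder).  The session starts mid-set unless
    ``start_index`` is given, follows the up-down rule, and ends four
    trials after the first reversal — or at the boundary rule when the
    staircase pins at either end without ever reversing.
    """
    if filaments is None:
        filaments = FilamentSet()
    n = len(filaments.forces)
    if start_index is None:
        start_index = n // 2
    if not 0 <= start_index < n:
        raise SessionError(f"start_index {start_index} outside the filament set")
    if true_threshold_g <= 0:
        raise SessionError("true threshold must be positive")
    rng = np.random.default_rng(seed)
    log_thr = math.log10(true_threshold_g)

    def withdraw_prob(idx: int) -> float:
        d = filaments.log_forces[idx] - log_thr
        if math.isinf(slope):
            return 1.0 if d > 0 else (0.5 if d == 0 else 0.0)
        return 1.0 / (1.0 + math.exp(-slope * d))

    trials: list[tuple[int, bool]] = []
    idx = start_index
    first_reversal: int | None = None
    while len(trials) < MAX_TRIALS:
        r = bool(rng.random() < withdraw_prob(idx))
        trials.append((idx, r))
        if first_reversal is None and len(trials) >= 2 and r != trials[0][1]:
            first_reversal = len(trials) - 1
        if first_reversal is not None and len(trials) >= first_reversal + 1 + POST_REVERSAL_TRIALS:
            break
        nxt = idx - 1 if r else idx + 1
        if first_reversal is None and (nxt < 0 or nxt > n - 1):
            break  # pinned at a boundary without ever reversing
        idx = min(max(nxt, 0), n - 1)
    return UpDownSession(trials=trials)


# -- Dixon coefficient table ------------------------------------------------


def _mle_threshold(levels: np.ndarray, responses: str, grid_step: float = 0.001) -> float:
    """ML threshold (in step units) of a response sequence.

    Model: P(withdraw at level l) = Phi(l - mu) with unit spread; the
    grid search spans the tested levels ± 3 steps.
    """
    lo, hi = levels.min() - 3.0, levels.max() + 3.0
    mu = np.arange(lo, hi + grid_step, grid_step)
    ll = np.zeros_like(mu)
    for l, r in zip(levels, responses):
        p = norm.cdf(l - mu)
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        ll += np.log(p) if r == WITHDRAW else np.log(1.0 - p)
    return float(mu[np.argmax(ll)])


def compute_k_table(max_len: int = 6) -> dict[str, float]:
    """Dixon k coefficients for all terminal response patterns.

    A pattern is the response string starting one trial before the first
    reversal; levels follow the up-down rule from a relative origin.
    ``k = mu_hat - l_final`` in units of the step size.
    """
    table: dict[str, float] = {}
    for length in range(2, max_len + 1):
        for bits in range(2**length):
            pattern = "".join(
                WITHDRAW if (bits >> (length - 1 - i)) & 1 else NO_WITHDRAW
                for i in range(length)
            )
            if len(set(pattern[:2])) == 1:
                # pattern must open with the first reversal's unlike pair
                continue
            levels = [0.0]
            for r in pattern[:-1]:
                levels.append(levels[-1] - 1.0 if r == WITHDRAW else levels[-1] + 1.0)
            levels = np.asarray(levels)
            mu = _mle_threshold(levels, pattern)
            table[pattern] = round(mu - levels[-1], 3)
    return table


def _load_k_table() -> dict[str, float]:
    with resources.files("gliamod").joinpath("data/dixon_k.json").open() as fh:
        return json.load(fh)


_K_TABLE: dict[str, float] | None = None


def pwt_updown(session: UpDownSession, filaments: FilamentSet | None = None) -> float:
    """50% paw-withdrawal threshold (g) from an up-down session.

    All-no-withdrawal sessions return the ceiling (stiffest) force,
    all-withdrawal sessions the floor force; otherwise the Dixon formula
    ``10**(Xf + k * delta)`` with the tabulated coefficient for the
    terminal response pattern.  If the staircase was clamped at a set
    boundary during the terminal pattern (so the tabulated level
    sequence does not apply), the coefficient is recomputed from the
    session's actual levels with the same likelihood rule.
    """
    global _K_TABLE
    if filaments is None:
        filaments = FilamentSet()
    session.validate(filaments)
    resp = session.responses()
    if WITHDRAW not in resp:
        return float(filaments.forces[-1])
    if NO_WITHDRAW not in resp:
        return float(filaments.forces[0])

    j = next(i for i, r in enumerate(resp) if r != resp[0])
    pattern = resp[j - 1 :]
    idx = [i for i, _ in session.trials[j - 1 :]]
    delta = filaments.delta
    x_f = float(filaments.log_forces[session.trials[-1][0]])

    # clamping at a bound breaks the pattern-implied level sequence
    clamped = any(
        (i == 0 and r == WITHDRAW) or (i == len(filaments.forces) - 1 and r == NO_WITHDRAW)
        for (i, _), r in zip(session.trials[j - 1 : -1], pattern[:-1])
    )
    if _K_TABLE is None:
        _K_TABLE = _load_k_table()
    if not clamped and pattern in _K_TABLE:
        k = _K_TABLE[pattern]
    else:
        levels = np.asarray(idx, dtype=float)
        k = _mle_threshold(levels, pattern) - levels[-1]
    return float(10.0 ** (x_f + k * delta))


def latency_with_cutoff(
    latencies: np.ndarray | list[float], cutoff: float
) -> tuple[np.ndarray, np.ndarray]:
    """Clamp response latencies (s) at a cutoff; flag censored values.

    Returns ``(clamped, censored)`` where ``censored`` marks latencies
    at or above the cutoff (the plate-test convention: 40 s hot,
    20 s cold).
    """
    lat = np.asarray(latencies, dtype=float)
    if np.any(lat < 0):
        raise ValueError("latencies must be non-negative")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return np.minimum(lat, cutoff), lat >= cutoff
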