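"""Model parameters for the networked PD with direct reciprocity.

The game is parameterized by the benefit-to-cost ratio ``r = b/c`` (the PD
*return*, with the cost of cooperating ``c = 1`` taken as the monetary unit),
the per-round probability ``delta`` that an agent revises her strategy, the
direct-reciprocity strength ``d``, and the predictive horizon ``h`` over which
a revising agent forecasts her cumulated income.

Reciprocating cooperators decide whether to resume playing with a known
defector according to the *biased* update rate ``delta_d = (1 - d) * delta``:
``d = 0`` is normal reciprocity (abstention lengths calibrated to the true
revision rate), ``d > 0`` super-normal (longer abstentions), ``d < 0``
sub-normal.  The extreme settings ``d = d_min = -(1/delta - 1)`` (no
reciprocity, ``delta_d = 1``) and ``d = d_max = 1`` (permanent link cutting,
``delta_d = 0``) are not admissible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field


__all__ = ["ModelParams", "RationalityPerturbation"]


@dataclass(frozen=True)
class RationalityPerturbation:
    """Bounded-rationality knobs applied to the revision step.

    ``gain_noise_sd``
        each computed expected gain is multiplied by ``1 + eps`` with
        ``eps ~ Normal(0, gain_noise_sd)``, emulating errors in computing
        model predictions.
    ``decision_flip_prob``
        the final keep/switch decision is inverted with this probability,
        emulating outright irrational choices.

    Zero settings recover the exact model bit-for-bit (no random draws are
    consumed).
    """

    gain_noise_sd: float = 0.0
    decision_flip_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.gain_noise_sd < 0:
            raise ValueError("gain_noise_sd must be >= 0")
        if not 0.0 <= self.decision_flip_prob < 0.5:
            raise ValueError("decision_flip_prob must be in [0, 0.5)")

    @property
    def is_identity(self) -> bool:
        return self.gain_noise_sd == 0.0 and self.decision_flip_prob == 0.0


@dataclass(frozen=True)
class ModelParams:
    """Validated parameter set ``(r, delta, d, h)`` with derived quantities.

    Parameters
    ----------
    r : float
        PD return b/c (> 0); with c = 1, the benefit is b = r.
    delta : float
        Per-round strategy-update probability, in (0, 1); 1/delta is the
        agents' inertia.
    d : float
        Direct-reciprocity strength, strictly inside (d_min, d_max).
    h : int or math.inf
        Predictive horizon (>= 1 game rounds).  ``math.inf`` selects the
        infinite-horizon decision rule: revisions compare per-round payoff
        rates, which reproduces the closed-form remain-C condition (used
        for the analytic reference cases; the forecast then has no finite
        table).
    perturbation : RationalityPerturbation, optional
        Bounded-rationality knobs; ``None`` means the exact model.
    """

    r: float
    delta: float
    d: float = 0.0
    h: int = 2
    perturbation: RationalityPerturbation | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"PD return r must be > 0, got {self.r}")
        if not 0.0 < self.delta < 1.0:
            raise ValueError(f"update rate delta must be in (0, 1), got {self.delta}")
        h_ok = (isinstance(self.h, int) and self.h >= 1) or (
            isinstance(self.h, float) and math.isinf(self.h) and self.h > 0
        )
        if not h_ok:
            raise ValueError(
                f"predictive horizon h must be an integer >= 1 or math.inf, got {self.h}"
            )
        if not self.d_min < self.d < self.d_max:
            raise ValueError(
                f"reciprocity d={self.d} outside the open admissible interval "
                f"({self.d_min}, {self.d_max}) for delta={self.delta}"
            )
        if not 0.0 < self.delta_d < 1.0:
            raise ValueError(f"derived delta_d={self.delta_d} outside (0, 1)")
        if not math.isinf(self.h) and self.delta * self.h > 0.3:
            warnings.warn(
                f"delta * h = {self.delta * self.h:.3g} > 0.3: the forecast "
                "neglects neighbors' strategy updates, which becomes a poor "
                "approximation for long horizons at this update rate",
                UserWarning,
                stacklevel=2,
            )

    @property
    def d_min(self) -> float:
        """Lower admissibility bound -(1/delta - 1) (no reciprocity)."""
        return -(1.0 / self.delta - 1.0)

    @property
    def d_max(self) -> float:
        """Upper admissibility bound 1 (permanent link cutting)."""
        return 1.0

    @property
    def delta_d(self) -> float:
        """Reciprocity-biased update rate (1 - d) * delta."""
        return (1.0 - self.d) * self.delta

    @property
    def b(self) -> float:
        """Benefit of an act of cooperation (cost c = 1)."""
        return self.r
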