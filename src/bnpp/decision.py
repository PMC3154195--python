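"""Expected-utility rule for reporting a model given its posterior.

With utilities for the four outcomes — true discovery U_TD, false
discovery U_FD (negative), true non-discovery U_TND, false non-discovery
U_FND (negative) — reporting maximizes expected utility when

    U_TD * P + U_FD * (1 - P)  >=  U_FND * P + U_TND * (1 - P),

i.e. when the posterior P reaches the threshold

    (U_TND - U_FD) / ((U_TD - U_FND) + (U_TND - U_FD)).

A posterior that looks unimpressive in absolute terms can still warrant
reporting when missed associations are costly relative to false leads.
Ties at the boundary report (discovery favoured).
"""

from __future__ import annotations

from dataclasses import dataclass


class UtilityError(ValueError):
    pass


@dataclass(frozen=True)
class UtilitySpec:
    """Outcome utilities; defaults are symmetric (threshold 1/2)."""

    u_td: float = 1.0
    u_fd: float = -1.0
    u_tnd: float = 1.0
    u_fnd: float = -1.0

    def __post_init__(self) -> None:
        if not self.u_td > self.u_fnd:
            raise UtilityError(
                "reporting a true model must beat missing it (u_td > u_fnd)"
            )
        if not self.u_tnd > self.u_fd:
            raise UtilityError(
                "withholding a false model must beat reporting it (u_tnd > u_fd)"
            )


def report_threshold(utilities: UtilitySpec) -> float:
    """Posterior above which reporting maximizes expected utility."""
    gain_true = utilities.u_td - utilities.u_fnd
    gain_false = utilities.u_tnd - utilities.u_fd
    return gain_false / (gain_true + gain_false)


def should_report(posterior: float, utilities: UtilitySpec) -> bool:
    """True iff the posterior meets the expected-utility reporting threshold."""
    if not 0 <= posterior <= 1:
        raise UtilityError(f"posterior out of [0, 1]: {posterior}")
    return posterior >= report_threshold(utilities)
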