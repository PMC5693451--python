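"""Parameter and conserved-quantity records for the carrier cycling cascade.

A carrier cycling cascade (CCC) is the minimal metabolic motif
``m0 -> m1 -> m2`` in which the first step consumes an active carrier
(ATP, NAD+ ...) and the second regenerates it, so that the total carrier
pool is a conserved moiety.  All rate constants live in units where the
catalytic turnover rates are O(1); time is measured in units of 1/kc.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass(frozen=True)
class CCCParams:
    """Rate and equilibrium constants of a single cascade.

    Parameters
    ----------
    kin : float
        Influx rate of the first metabolite m0 (concentration/time).
    kleak : float
        First-order leak (dilution) rate of m0 (1/time).
    kout : float
        First-order efflux rate of the product m2 (1/time).
    kc : float
        Turnover rate of the active-carrier-consuming step (1/time).
    kp : float
        Turnover rate of the active-carrier-producing step (1/time).
    K0 : float
        Dissociation constant of the c.m0 complex (concentration).
    K1 : float
        Dissociation constant of the c*.m1 complex (concentration).
    ka0, ka1 : float
        Association rate constants of the two binding steps; used only by
        the full mass-action model (the reduced models assume binding
        equilibrium).  Dissociation rates are kd = ka * K.
    """

    kin: float = 0.9
    kleak: float = 0.0
    kout: float = 1.0
    kc: float = 1.0
    kp: float = 1.0
    K0: float = 1e-3
    K1: float = 1e-3
    ka0: float = 1e6
    ka1: float = 1e6

    def __post_init__(self) -> None:
        for name in ("kin", "kleak", "kout", "ka0", "ka1"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("kc", "kp", "K0", "K1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    def replace(self, **changes) -> "CCCParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class ConservedTriple:
    """The conserved quantities of one cascade.

    cpool = [c]_t + [c*]_t is the total carrier pool; csum = [c]_t + [m1]
    is conserved because producing one m1 consumes exactly one active
    carrier; cdiff_star = [c*]_t - [m1] is the complementary combination,
    with cpool = csum + cdiff_star.
    """

    cpool: float
    csum: float
    cdiff_star: float

    def __post_init__(self) -> None:
        if self.cpool < 0:
            raise ValueError("cpool must be >= 0")
        if abs(self.cpool - (self.csum + self.cdiff_star)) > 1e-9 * max(1.0, abs(self.cpool)):
            raise ValueError("cpool must equal csum + cdiff_star")

    @classmethod
    def from_pool_sum(cls, cpool: float, csum: float) -> "ConservedTriple":
        return cls(cpool=cpool, csum=csum, cdiff_star=cpool - csum)


#: Default conserved quantities used throughout the simulation presets.
DEFAULT_CONSERVED = ConservedTriple.from_pool_sum(2.0, 2.0)
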