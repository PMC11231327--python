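"""Inter-box volume transports and advective tracer tendencies.

The circulation is prescribed: every directed flux is a fixed fraction of
the Southern Ocean upwelling strength psi.  Deep Southern water upwells at
rate psi; a fraction ``f_smoc`` subducts back (the SMOC, Antarctic Bottom
Water path) and circulates through the deep Atlantic and Pacific, while the
remainder feeds the surface limbs that sink in the North Atlantic (the
AMOC, with strength ``f_amoc * psi``, half of which arrives from the
surface Pacific).  An optional bidirectional exchange ``kappa`` between
adjacent boxes represents turbulent mixing.  Tracer advection is upstream
(donor-cell) differencing.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .boxes import SV, Box, BoxGeometry, OceanState, TRACERS

#: unordered adjacent pairs that exchange kappa (Fig-4 topology adjacency)
MIXING_PAIRS = (
    ("SA", "DA"), ("SS", "DS"), ("SP", "DP"),
    ("SA", "SS"), ("SS", "SP"), ("DA", "DS"), ("DS", "DP"),
)

#: default deep Pacific-to-Southern return flow as a fraction of psi.
#: The deep Pacific exchanges water with the deep Southern Ocean in both
#: directions (Pacific Deep Water returns southward at depth); without it
#: the Pacific column would recycle its own export indefinitely and pin
#: surface Pacific nutrients to deep Southern values.
DEFAULT_F_RETURN = 0.35

#: default directed fluxes as fractions of psi (mass-balanced per box)
DEFAULT_FRACTIONS: dict[tuple[str, str], float] = {
    ("DS", "SS"): 1.00,   # Southern Ocean upwelling
    ("SS", "DS"): 0.55,   # SMOC subduction
    ("SS", "SA"): 0.50,
    ("SP", "SS"): 0.05,
    ("SP", "SA"): 0.50,   # half the AMOC comes from the surface Pacific
    ("SA", "DA"): 1.00,   # AMOC sinking
    ("DA", "DS"): 1.00,
    ("DS", "DP"): 0.55 + DEFAULT_F_RETURN,
    ("DP", "DS"): DEFAULT_F_RETURN,
    ("DP", "SP"): 0.55,
}

_BALANCE_RTOL = 1e-12


def _fractions(f_amoc: float, f_smoc: float,
               f_return: float = DEFAULT_F_RETURN) -> dict[tuple[str, str], float]:
    if f_smoc < 0.5 * f_amoc:
        raise ValueError("f_smoc must be at least half of f_amoc for a "
                         "non-negative surface Pacific-to-Southern flux")
    if f_return < 0:
        raise ValueError("f_return must be non-negative")
    return {
        ("DS", "SS"): f_amoc,
        ("SS", "DS"): f_smoc,
        ("SS", "SA"): 0.5 * f_amoc,
        ("SP", "SS"): f_smoc - 0.5 * f_amoc,
        ("SP", "SA"): 0.5 * f_amoc,
        ("SA", "DA"): f_amoc,
        ("DA", "DS"): f_amoc,
        ("DS", "DP"): f_smoc + f_return,
        ("DP", "DS"): f_return,
        ("DP", "SP"): f_smoc,
    }


@dataclasses.dataclass(frozen=True)
class TransportNetwork:
    """Directed volume fluxes (Sv) plus bidirectional mixing exchanges."""

    fluxes: dict[tuple[str, str], float]
    kappa: float = 0.0
    kappa_pairs: tuple[tuple[str, str], ...] = MIXING_PAIRS

    def __post_init__(self) -> None:
        for (src, dst), f in self.fluxes.items():
            if src not in Box.__members__ or dst not in Box.__members__:
                raise KeyError(f"unknown box in flux ({src}, {dst})")
            if f < 0:
                raise ValueError(f"negative flux {src}->{dst}")
        if self.kappa < 0:
            raise ValueError("negative kappa")
        imbalance = np.abs(self.imbalance())
        scale = max(sum(self.fluxes.values()), 1.0)
        if imbalance.max() > _BALANCE_RTOL * scale:
            raise ValueError(f"transport network is not mass balanced: {imbalance}")

    def imbalance(self) -> np.ndarray:
        """Per-box inflow minus outflow, Sv (zero for a balanced network)."""
        net = np.zeros(6)
        for (src, dst), f in self.fluxes.items():
            net[Box[dst]] += f
            net[Box[src]] -= f
        return net

    def flux(self, src: str, dst: str) -> float:
        return self.fluxes.get((src, dst), 0.0)

    @property
    def amoc(self) -> float:
        return self.flux("SA", "DA")

    @property
    def smoc(self) -> float:
        return self.flux("SS", "DS")

    def matrix(self, geom: list[BoxGeometry]) -> np.ndarray:
        """Linear tendency operator M (s-1): dC/dt = M @ C.

        Includes both the directed (donor-cell) fluxes and the kappa
        exchanges; column sums weighted by box volume vanish, so any
        source-free tracer is conserved.
        """
        vol = np.array([g.volume for g in geom])
        m = np.zeros((6, 6))
        for (src, dst), f in self.fluxes.items():
            i, j = Box[dst], Box[src]
            m[i, j] += f * SV / vol[i]
            m[j, j] -= f * SV / vol[j]
        k = self.kappa * SV
        if k > 0:
            for a, b in self.kappa_pairs:
                i, j = Box[a], Box[b]
                m[i, j] += k / vol[i]
                m[i, i] -= k / vol[i]
                m[j, i] += k / vol[j]
                m[j, j] -= k / vol[j]
        return m

    def to_frame(self) -> pd.DataFrame:
        """Serialize the directed fluxes for inspection (source, dest, Sv)."""
        rows = [(s, d, f) for (s, d), f in sorted(self.fluxes.items())]
        return pd.DataFrame(rows, columns=["source", "destination", "flux_sv"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, kappa: float = 0.0) -> "TransportNetwork":
        fluxes = {(r.source, r.destination): float(r.flux_sv)
                  for r in frame.itertuples()}
        return cls(fluxes=fluxes, kappa=kappa)


def build_transport(psi: float, f_amoc: float = 1.0, f_smoc: float = 0.55,
                    kappa: float = 0.0,
                    fractions: Mapping[tuple[str, str], float] | None = None,
                    f_return: float = DEFAULT_F_RETURN) -> TransportNetwork:
    """Build the transport network for upwelling strength ``psi`` (Sv).

    ``f_return`` sets the bidirectional deep Pacific-Southern exchange
    (DP->DS return flow, with DS->DP raised to keep the balance).
    ``fractions`` overrides the whole directed network (entries are
    fractions of psi); the result must still be mass balanced per box.
    """
    if psi < 0:
        raise ValueError("psi must be non-negative")
    if fractions is None:
        fractions = _fractions(f_amoc, f_smoc, f_return)
    fluxes = {pair: psi * frac for pair, frac in fractions.items()}
    return TransportNetwork(fluxes=fluxes, kappa=kappa)


def advective_tendency(state: OceanState | np.ndarray, net: TransportNetwork,
                       geom: list[BoxGeometry]):
    """Transport tendency for every tracer.

    With an :class:`OceanState` input, returns a ``{tracer: (6,) array}``
    dict in the tracer's customary concentration unit per second; with a
    plain ``(..., 6)`` concentration array, returns the matching tendency
    array (unit of input per second).
    """
    m = net.matrix(geom)
    if isinstance(state, OceanState):
        return {t: getattr(state, t) @ m.T for t in TRACERS}
    arr = np.asarray(state, dtype=float)
    return arr @ m.T
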