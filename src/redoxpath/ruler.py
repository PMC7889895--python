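"""Empirical electron-transfer rate ruler and redox-chain energetics.

The exergonic branch is the classic log-linear ruler for intraprotein
tunneling at room temperature:

    log10 k = 13 - (1.2 - 0.8 ρ)(R - 3.6) - 3.1 (ΔG + λ)² / λ

with R the edge-to-edge donor-acceptor distance (Å), ΔG the driving force
(eV, negative downhill), λ the reorganization energy (eV) and ρ the packing
density of the intervening medium (fraction of the volume between the
cofactors filled with atoms).  At R = 3.6 Å (van der Waals contact) and
activationless driving force (ΔG = -λ) the ruler reaches its 10¹³ s⁻¹
ceiling.

Endergonic (uphill, ΔG > 0) steps are priced by detailed balance: the uphill
rate equals the reverse (downhill) rate attenuated by one decade per
0.06 eV of uphill driving force at 298 K:

    log10 k(+ΔG) = log10 k(-ΔG) - ΔG / 0.06

The two branches join continuously at ΔG = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atoms import CofactorGroup, Structure
from .geometry import distance, edge_to_edge, group_center

__all__ = ["RedoxCenter", "ETStep", "delta_g", "et_rate", "chain_report"]

#: thermal decade constant at 298 K, eV per factor-of-ten in rate
TEMPERATURE_TERM = 0.06

#: van der Waals contact distance where the distance penalty vanishes, Å
CONTACT_DISTANCE = 3.6


@dataclass
class RedoxCenter:
    """A redox cofactor with an optional midpoint potential (volts)."""

    label: str
    cofactor: CofactorGroup
    midpoint_potential: float | None = None  # volts vs SHE


def delta_g(e_donor: float, e_acceptor: float) -> float:
    """One-electron driving force in eV from midpoint potentials in volts.

    ΔG = E_donor - E_acceptor: positive means the step is uphill
    (the acceptor is harder to reduce than the donor is to oxidize).
    Antisymmetric under donor/acceptor exchange.
    """
    if not (np.isfinite(e_donor) and np.isfinite(e_acceptor)):
        raise ValueError("potentials must be finite")
    return float(e_donor - e_acceptor)


def et_rate(
    R: float,
    delta_g_ev: float,
    lambda_reorg: float,
    rho: float,
    temperature_term: float = TEMPERATURE_TERM,
) -> tuple[float, float]:
    """Electron-tunneling rate from the empirical ruler.

    Parameters
    ----------
    R : edge-to-edge distance, Å (> 0; below 3.6 Å the packing expression is
        outside its calibrated range — a warning-level concern, not an error).
    delta_g_ev : driving force, eV; positive = endergonic (uphill).
    lambda_reorg : reorganization energy, eV (> 0).
    rho : packing density of the intervening medium, in (0, 1].
    temperature_term : eV per decade for the uphill Boltzmann penalty.

    Returns ``(log10_rate, rate_per_s)``.
    """
    if R <= 0:
        raise ValueError("distance R must be positive")
    if lambda_reorg <= 0:
        raise ValueError("reorganization energy must be positive")
    if not (0 < rho <= 1):
        raise ValueError("packing density rho must lie in (0, 1]")
    if temperature_term <= 0:
        raise ValueError("temperature_term must be positive")

    def exergonic_log10(dg: float) -> float:
        return (
            13.0
            - (1.2 - 0.8 * rho) * (R - CONTACT_DISTANCE)
            - 3.1 * (dg + lambda_reorg) ** 2 / lambda_reorg
        )

    if delta_g_ev <= 0:
        log10_k = exergonic_log10(delta_g_ev)
    else:
        # detailed balance: uphill rate = reverse downhill rate × 10^(-ΔG/kT')
        log10_k = exergonic_log10(-delta_g_ev) - delta_g_ev / temperature_term
    return log10_k, 10.0**log10_k


@dataclass
class ETStep:
    """One donor→acceptor step of a redox chain."""

    donor: str
    acceptor: str
    center_to_center: float  # Å
    edge_distance_R: float  # Å
    edge_pair: tuple[str, str]
    delta_g: float | None  # eV; + = endergonic
    lambda_reorg: float | None
    rho_packing: float | None
    log10_rate: float | None
    rate: float | None

    def as_row(self) -> dict:
        return {
            "donor": self.donor,
            "acceptor": self.acceptor,
            "center_to_center": round(self.center_to_center, 1),
            "edge_to_edge": round(self.edge_distance_R, 1),
            "edge_pair": " -> ".join(self.edge_pair),
            "delta_g_ev": None if self.delta_g is None else round(self.delta_g, 3),
            "log10_rate": None if self.log10_rate is None else round(self.log10_rate, 2),
            "rate_per_s": self.rate,
        }


def chain_report(
    centers: list[RedoxCenter],
    lambda_reorg: float = 0.7,
    rho: float = 0.77,
    temperature_term: float = TEMPERATURE_TERM,
) -> pd.DataFrame:
    """Distances and (where potentials are known) rates along a redox chain.

    For every consecutive pair: center-to-center and edge-to-edge distance,
    ΔG from the two midpoint potentials when both are supplied (otherwise the
    energetic columns stay empty), and the ruler rate with R taken as the
    edge-to-edge distance.  A final "span" row reports the cumulative
    center-to-center sum and the direct first-to-last center distance.
    """
    if len(centers) < 2:
        raise ValueError("a chain needs at least two redox centers")
    steps: list[ETStep] = []
    for donor, acceptor in zip(centers, centers[1:]):
        c2c = distance(group_center(donor.cofactor), group_center(acceptor.cofactor))
        e2e, (pa, pb) = edge_to_edge(donor.cofactor, acceptor.cofactor)
        if donor.midpoint_potential is not None and acceptor.midpoint_potential is not None:
            dg = delta_g(donor.midpoint_potential, acceptor.midpoint_potential)
            log10_k, k = et_rate(e2e, dg, lambda_reorg, rho, temperature_term)
        else:
            dg = log10_k = k = None
        steps.append(
            ETStep(
                donor=donor.label,
                acceptor=acceptor.label,
                center_to_center=c2c,
                edge_distance_R=e2e,
                edge_pair=(f"{pa.residue_label}/{pa.name}", f"{pb.residue_label}/{pb.name}"),
                delta_g=dg,
                lambda_reorg=None if dg is None else lambda_reorg,
                rho_packing=None if dg is None else rho,
                log10_rate=log10_k,
                rate=k,
            )
        )
    table = pd.DataFrame([s.as_row() for s in steps])
    span_sum = float(sum(s.center_to_center for s in steps))
    span_direct = distance(group_center(centers[0].cofactor), group_center(centers[-1].cofactor))
    table.attrs["span_sum_of_steps"] = span_sum
    table.attrs["span_direct"] = float(span_direct)
    return table
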