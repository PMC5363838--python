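"""Respiratory-chain bioenergetic efficiency.

The efficiency of a respiratory chain is the fraction of the redox Gibbs
energy that ends up in the proton motive force:

    efficiency = q * pmf / (2 * span)

with q the number of charges translocated across the membrane per 2
electrons, pmf the proton motive force (V) and span the redox potential
difference between donor and acceptor couples per 2 electrons (V).

Presets (charge stoichiometries inferred so that the standard textbook
chains come out right at pmf = 0.18 V over the NADH -> O2 span of 1.14 V):

* ``canonical`` - NADH dehydrogenase + bc1 complex + proton-pumping
  heme-copper oxidase: 10 charges / 2e, efficiency ~79%.
* ``bd`` - chain terminated by a cytochrome bd quinol oxidase, which
  accepts electrons from quinols (bypassing complex III) and does not
  pump protons: 4 charges / 2e, efficiency ~32%.
* ``denitrification`` - NADH dehydrogenase + bc1 feeding the denitrification
  reductases (NAR/NIR/NOR/NOS), none of which pumps protons: 6 charges / 2e
  over the NADH -> NO2-/N2 span of 1.30 V, efficiency ~42%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass


class BioenergeticsError(ValueError):
    pass


@dataclass(frozen=True)
class RespiratoryChain:
    """A respiratory chain characterized by its charge-translocation
    stoichiometry and the redox span it operates over.

    Parameters
    ----------
    name : str
        Label ("canonical", "bd", ...).
    charges_per_2e : float
        Charges translocated across the membrane per 2 electrons.
    pmf : float
        Proton motive force, V.  Default 0.18 V.
    redox_span : float
        Donor-to-acceptor redox potential difference, V per 2 electrons.
        Default 1.14 V (NADH -> O2).
    """

    name: str
    charges_per_2e: float
    pmf: float = 0.18
    redox_span: float = 1.14

    def __post_init__(self) -> None:
        if self.charges_per_2e < 0:
            raise BioenergeticsError("charges_per_2e must be >= 0")
        if self.pmf < 0:
            raise BioenergeticsError("pmf must be >= 0")
        if self.redox_span <= 0:
            raise BioenergeticsError("redox span must be positive")


def chain_efficiency(chain: RespiratoryChain) -> float:
    """Fraction of the redox energy conserved as proton motive force.

    >>> round(chain_efficiency(PRESETS["bd"]), 3)
    0.316
    """
    eff = chain.charges_per_2e * chain.pmf / (2.0 * chain.redox_span)
    if eff > 1.0:
        warnings.warn(
            f"chain {chain.name!r}: computed efficiency {eff:.2f} > 1; "
            "check charge stoichiometry and span",
            stacklevel=2,
        )
    return eff


PRESETS = {
    "canonical": RespiratoryChain("canonical", charges_per_2e=10.0),
    "bd": RespiratoryChain("bd", charges_per_2e=4.0),
    "denitrification": RespiratoryChain(
        "denitrification", charges_per_2e=6.0, redox_span=1.30
    ),
}


def get_chain(name: str, pmf: float | None = None) -> RespiratoryChain:
    """Look up a preset chain, optionally at a non-default proton motive force."""
    try:
        chain = PRESETS[name]
    except KeyError:
        raise BioenergeticsError(
            f"unknown chain {name!r}; presets: {sorted(PRESETS)}"
        ) from None
    if pmf is not None:
        chain = RespiratoryChain(chain.name, chain.charges_per_2e, pmf, chain.redox_span)
    return chain
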