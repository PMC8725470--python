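"""Packaged example networks with reference decision vectors.

Three classic bistable motifs ship with the package: the Edelstein
autocatalytic network, a futile signaling cycle with a two-state kinase, and
a prion-like double-phosphorylation motif.  Each fixture carries a reference
decision vector — rate constants, concentrations, and conservation totals at
which the network sits at a saddle-node — so the saddle condition, the
continuation diagrams, and the dose–response machinery can be exercised
without rerunning the global search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .conservation import ConservationBasis, conservation_basis
from .network import CRNTMatrices, ReactionNetwork, build_crnt_matrices, parse_reaction_text
from .odes import IndependentSystem, select_independent_odes

__all__ = ["Fixture", "edelstein", "futile_cycle", "prion", "FIXTURES"]


@dataclass
class Fixture:
    """A packaged network plus the configuration its analysis uses."""

    name: str
    network_text: str
    response: str                      # readout species
    signal_species: tuple[str, ...]    # species summed by the signal total
    species_order: tuple[str, ...] | None = None
    # reference decision vector: rate constants by symbol name, concentrations
    # by species name, conservation totals keyed by their species tuple
    rates: dict[str, float] = field(default_factory=dict)
    concentrations: dict[str, float] = field(default_factory=dict)
    totals: dict[tuple[str, ...], float] = field(default_factory=dict)
    expected_uniterminal: bool | None = None
    expected_bistable: bool = True

    def network(self) -> ReactionNetwork:
        return parse_reaction_text(self.network_text, species_order=self.species_order)

    def matrices(self) -> CRNTMatrices:
        return build_crnt_matrices(self.network())

    def basis(self, rng_seed: int = 0) -> ConservationBasis:
        return conservation_basis(self.matrices(), rng_seed=rng_seed)

    def independent_system(self, rng_seed: int = 0) -> IndependentSystem:
        matrices = self.matrices()
        basis = conservation_basis(matrices, rng_seed=rng_seed)
        signal = signal_total_symbol(basis, self.signal_species)
        return select_independent_odes(matrices, basis, self.response, signal=signal)

    @property
    def signal_value(self) -> float:
        return self.totals[tuple(sorted(self.signal_species))]


def signal_total_symbol(basis: ConservationBasis, signal_species: tuple[str, ...]):
    """Find the conservation total whose support equals the given species."""
    want = set(signal_species)
    for j in range(basis.lam):
        support = {
            basis.species[i]
            for i in range(len(basis.species))
            if basis.B[i, j] != 0
        }
        if support == want:
            return basis.total_symbols[j]
    raise ValueError(f"no conservation law with support {sorted(want)}")


def edelstein() -> Fixture:
    """Autocatalytic network with substrate inhibition; uniterminal.

    Species A replicates autocatalytically and is sequestered by B into the
    complex C.  Signal: the conserved total B + C; response: [A].  The
    reference decision vector places the system exactly at the upper fold of
    the S-shaped equilibrium curve.
    """
    return Fixture(
        name="edelstein",
        network_text=(
            "A -> 2A; 2A -> A; A + B -> C; C -> A + B; C -> B; B -> C"
        ),
        response="A",
        signal_species=("B", "C"),
        rates={
            "k1": 0.05024595,
            "k2": 0.01029913,
            "k3": 0.03592955,
            "k4": 0.01027423,
            "k5": 0.01272131,
            "k6": 0.01006076,
        },
        concentrations={"A": 1.48685156, "B": 2.07275022, "C": 5.72214036},
        totals={("B", "C"): 7.79489058},
        expected_uniterminal=True,
        expected_bistable=True,
    )


def futile_cycle() -> Fixture:
    """Futile signaling cycle with a two-state kinase; biterminal.

    A kinase interconverts between forms E1 and E2, both of which bind the
    substrate S; the enzyme-substrate complexes release either S or the
    phosphorylated form Sp, which decays back to S.  Signal: total substrate
    S_tot; response: [Sp].
    """
    return Fixture(
        name="futile_cycle",
        network_text="\n".join(
            [
                "S + E1 -> E1S",
                "E1S -> S + E1",
                "E1S -> Sp + E1",
                "S + E2 -> E2S",
                "E2S -> S + E2",
                "E2S -> Sp + E2",
                "Sp -> S",
                "E1 -> E2",
                "E2 -> E1",
                "E1S -> E2S",
                "E2S -> E1S",
            ]
        ),
        response="Sp",
        signal_species=("S", "E1S", "Sp", "E2S"),
        rates={
            "k1": 0.738028,
            "k2": 3.316128,
            "k3": 0.001800,
            "k4": 0.050541,
            "k5": 0.029997,
            "k6": 0.53685,
            "k7": 0.065141,
            "k8": 2.310671,
            "k9": 0.001081,
            "k10": 0.008850,
            "k11": 3.437878,
        },
        concentrations={
            "E1S": 957.287983,
            "Sp": 605.457182,
            "E2": 136.645046,
            "E2S": 70.255623,
            # E1 and S recovered from the conservation totals
            "E1": 100.925492,
            "S": 39.512947,
        },
        totals={
            tuple(sorted(("E1", "E1S", "E2", "E2S"))): 1265.114144,
            tuple(sorted(("S", "E1S", "Sp", "E2S"))): 1672.513735,
        },
        expected_uniterminal=False,
        expected_bistable=True,
    )


def prion() -> Fixture:
    """Prion-like kinase conformation switch with double phosphorylation.

    The kinase exists in an inactive form E1 and an active form E2; the
    conversion is itself catalyzed through the dimers E1E2 and E2E1 (a
    prion-like mechanism).  E2 phosphorylates the substrate twice,
    S -> Sp -> Spp, through the complexes SE2 and SpE2.  Signal: total
    substrate S_tot; response: [Spp].
    """
    return Fixture(
        name="prion",
        network_text="\n".join(
            [
                "E1E2 -> E1 + E2",
                "E1 + E2 -> E1E2",
                "E1 + E2 -> E2E1",
                "E2E1 -> E1 + E2",
                "E1E2 -> 2E1",
                "E2E1 -> 2E2",
                "S + E2 -> SE2",
                "SE2 -> S + E2",
                "SE2 -> Sp + E2",
                "Sp + E2 -> SpE2",
                "SpE2 -> Sp + E2",
                "SpE2 -> Spp + E2",
                "Spp -> Sp",
                "Sp -> S",
            ]
        ),
        response="Spp",
        signal_species=("S", "Sp", "SE2", "Spp", "SpE2"),
        species_order=(
            "E1", "E2", "E1E2", "E2E1", "S", "Sp", "SE2", "Spp", "SpE2"
        ),
        rates={
            "k1": 27.963833,
            "k2": 2.417993,
            "k3": 2.121228,
            "k4": 48.342142,
            "k5": 0.910340,
            "k6": 1.802118,
            "k7": 17.019827,
            "k8": 92.473965,
            "k9": 0.021611,
            "k10": 0.782488,
            "k11": 3.692336,
            "k12": 0.205743,
            "k13": 0.063297,
            "k14": 0.235401,
        },
        concentrations={
            "E1": 14.749224,
            "E2": 18.117522,
            "E1E2": 22.377604,
            "E2E1": 11.304051,
            "S": 27.001718,
            "Sp": 8.264281,
            "SE2": 90.016969,
            "Spp": 97.695329,
            "SpE2": 30.056006,
        },
        totals={
            tuple(sorted(("S", "Sp", "SE2", "Spp", "SpE2"))): 253.034303,
            tuple(sorted(("E1", "E2", "E1E2", "E2E1", "SE2", "SpE2"))): 220.303031,
        },
        expected_uniterminal=False,
        expected_bistable=True,
    )


FIXTURES = {"edelstein": edelstein, "futile_cycle": futile_cycle, "prion": prion}
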