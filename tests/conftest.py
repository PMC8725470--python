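"""Shared fixtures: the packaged networks and their derived objects.

Session scope keeps the symbolic work (parsing, reduction, steady-state
solves) to one pass for the whole suite.
"""

from __future__ import annotations

import numpy as np
import pytest
import sympy as sp

from crnswitch import fixtures as fx
from crnswitch.steady_state import solve_steady_state


@pytest.fixture(scope="session")
def edelstein():
    return fx.edelstein()


@pytest.fixture(scope="session")
def futile():
    return fx.futile_cycle()


@pytest.fixture(scope="session")
def prion():
    return fx.prion()


@pytest.fixture(scope="session")
def edelstein_system(edelstein):
    return edelstein.independent_system()


@pytest.fixture(scope="session")
def futile_system(futile):
    return futile.independent_system()


@pytest.fixture(scope="session")
def prion_system(prion):
    return prion.independent_system()


@pytest.fixture(scope="session")
def edelstein_param(edelstein_system):
    return solve_steady_state(edelstein_system)


@pytest.fixture(scope="session")
def futile_param(futile_system):
    return solve_steady_state(futile_system)


@pytest.fixture(scope="session")
def prion_param(prion_system):
    return solve_steady_state(prion_system)


def rates_vector(fixture) -> list[float]:
    return [fixture.rates[f"k{i+1}"] for i in range(len(fixture.rates))]


def independent_values(fixture, system) -> np.ndarray:
    names = [system.network.species[i] for i in system.independent_indices]
    return np.array([fixture.concentrations[n] for n in names])


def fixed_totals_map(fixture, system) -> dict[sp.Symbol, float]:
    """Conservation totals other than the signal, keyed by symbol."""
    basis = system.basis
    out = {}
    for j in range(basis.lam):
        sym = basis.total_symbols[j]
        if sym == system.signal:
            continue
        support = tuple(
            sorted(
                basis.species[i]
                for i in range(len(basis.species))
                if basis.B[i, j] != 0
            )
        )
        out[sym] = fixture.totals[support]
    return out


def make_normal_form():
    """A hand-built one-dimensional system F = signal - x**2.

    The canonical fold: equilibria x = +/-sqrt(signal) collide at signal 0.
    Used to exercise continuation and the saddle-node check against the
    analytically known answer.
    """
    from crnswitch.network import parse_reaction_text
    from crnswitch.conservation import ConservationBasis
    from crnswitch.odes import IndependentSystem

    net = parse_reaction_text("X -> Y; Y -> X")
    cX, cY = net.concentration_symbols
    C1 = sp.Symbol("C1", positive=True)
    basis = ConservationBasis(
        B=sp.ImmutableMatrix([[1], [1]]),
        total_symbols=(C1,),
        species=("X", "Y"),
        conc_symbols=net.concentration_symbols,
    )
    from crnswitch.network import build_crnt_matrices

    return IndependentSystem(
        network=net,
        matrices=build_crnt_matrices(net),
        basis=basis,
        independent_indices=(0,),
        eliminated={},
        F=sp.ImmutableMatrix([C1 - cX**2]),
        signal=C1,
        response=cX,
    )
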