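"""Shared fixtures and independent oracles.

The envelope oracle enumerates every isotopologue composition exhaustively
(multinomial over per-element isotope counts) and aggregates by neutron
excess — a brute-force path that shares no code with the package's
convolution implementation.
"""

from __future__ import annotations

from itertools import product
from math import factorial, prod

import numpy as np
import pytest

import residuescreen as rs
from residuescreen.formula import ELECTRON_MASS, isotope_table


def enumerate_envelope(counts: dict[str, int], charge: int = 0):
    """Exhaustive isotopologue enumeration aggregated by neutron excess.

    Returns (offsets, centroid masses, relative abundances) for every
    aggregate with non-zero probability. Only feasible for small formulas.
    """
    table = isotope_table()

    def compositions(n, k):
        if k == 1:
            yield (n,)
            return
        for first in range(n + 1):
            for rest in compositions(n - first, k - 1):
                yield (first,) + rest

    per_element = []
    for sym, n in counts.items():
        isos = table[sym]
        base = isos[0].mass_number
        opts = []
        for comp in compositions(n, len(isos)):
            p = factorial(n)
            for c in comp:
                p //= factorial(c)
            p *= prod(iso.abundance ** c for iso, c in zip(isos, comp))
            mass = sum(iso.mass * c for iso, c in zip(isos, comp))
            off = sum((iso.mass_number - base) * c for iso, c in zip(isos, comp))
            opts.append((off, p, mass))
        per_element.append(opts)

    agg_p: dict[int, float] = {}
    agg_w: dict[int, float] = {}
    for combo in product(*per_element):
        off = sum(c[0] for c in combo)
        p = prod(c[1] for c in combo)
        mass = sum(c[2] for c in combo)
        agg_p[off] = agg_p.get(off, 0.0) + p
        agg_w[off] = agg_w.get(off, 0.0) + p * mass
    offs = sorted(agg_p)
    p = np.array([agg_p[o] for o in offs])
    m = np.array([agg_w[o] / agg_p[o] for o in offs])
    if charge:
        m = (m - charge * ELECTRON_MASS) / abs(charge)
    return np.array(offs), m, p / p.max()


@pytest.fixture(scope="session")
def panel():
    """Bundled 121-compound library, parameter frame and nominal curves."""
    return rs.demo_dataset()


@pytest.fixture(scope="session")
def atrazine(panel):
    lib, _, _ = panel
    return lib["Atrazine"]


@pytest.fixture()
def noiseless():
    return rs.NoiseModel(mass_sigma=0.0, rt_sigma=0.0, area_cv=0.0, seed=0)


def perfect_feature(compound, area=1e7, prune=0.001, sample_id="s1"):
    """A feature whose every attribute equals the library expectation."""
    env = rs.isotope_envelope(compound.formula, compound.adduct, prune=prune)
    cluster = tuple((mz, area * rel) for mz, rel in env)
    ms2 = tuple((f, area * 0.1) for f in compound.fragments) or None
    return rs.Feature(
        mz=env.peaks[0][0],
        rt=compound.expected_rt,
        area=area,
        height=area,
        isotope_cluster=cluster,
        ms2=ms2,
        sample_id=sample_id,
        polarity=compound.polarity,
    )
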