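"""Independent oracles used by the tests.

The brute-force isotopologue oracle literally enumerates every per-atom
isotope assignment element by element (2^n / 3^n products), sharing only
the pinned isotope catalog with the implementation — none of the
multinomial/convolution machinery.
"""

import itertools

from nitroquant.chem import DEFAULT_CATALOG


def brute_force_pattern(composition, catalog=DEFAULT_CATALOG) -> dict[float, float]:
    """Exact isotopologue pattern {rounded mass: probability} by enumeration."""
    total = {0.0: 1.0}
    for token, count in composition.items():
        isotopes = catalog.isotopes(token)
        element: dict[float, float] = {}
        for assignment in itertools.product(range(len(isotopes)), repeat=count):
            mass = sum(isotopes[i].mass for i in assignment)
            prob = 1.0
            for i in assignment:
                prob *= isotopes[i].abundance
            key = round(mass, 9)
            element[key] = element.get(key, 0.0) + prob
        merged: dict[float, float] = {}
        for m0, p0 in total.items():
            for m1, p1 in element.items():
                key = round(m0 + m1, 9)
                merged[key] = merged.get(key, 0.0) + p0 * p1
        total = merged
    return total
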