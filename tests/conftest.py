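import datetime as dt

import numpy as np
import pytest

from atikit.trends_io import WeeklySeries, assemble_panel

MONDAY = dt.date(2020, 1, 6)


def make_panel(values, terms=None, geo="XX", role="absolutist", start=MONDAY):
    """Build a TrendsPanel from a terms x weeks array of values in [0, 100]."""
    values = np.asarray(values, dtype=float)
    if terms is None:
        terms = [f"w{j}" for j in range(values.shape[0])]
    weeks = tuple(start + i * dt.timedelta(days=7) for i in range(values.shape[1]))
    series = [
        WeeklySeries(term=t, geo=geo, week_start=weeks, values=values[j])
        for j, t in enumerate(terms)
    ]
    return assemble_panel(series, role=role)


def exact_correlation_pair(rho, n, seed=0):
    """Two length-n series whose sample Pearson correlation is exactly rho.

    Draw x and e, orthogonalise e against x, standardise both, and mix:
    y = rho * x_std + sqrt(1 - rho^2) * e_std.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    e = rng.standard_normal(n)
    xc = (x - x.mean()) / x.std(ddof=0)
    e = e - e.mean()
    e = e - (e @ xc) / (xc @ xc) * xc
    ec = e / e.std(ddof=0)
    y = rho * xc + np.sqrt(1.0 - rho**2) * ec
    return xc, y


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
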