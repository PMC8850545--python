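"""Reliability-gated average index over a term panel.

The Absolute Thinking Index (ATI) for a week is the unweighted arithmetic
mean, over all dictionary terms, of each term's relative search volume that
week, kept on the raw 0–100 scale so intervention effects read directly as
index points. Internal consistency of the multi-term index is checked with
Cronbach's alpha before averaging; a low alpha raises a logged warning, never
a silent pass.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .trends_io import TrendsPanel

__all__ = ["AtiSeries", "AtiIndexError", "ReliabilityWarning",
           "cronbach_alpha", "compute_ati"]

logger = logging.getLogger(__name__)


class AtiIndexError(ValueError):
    """Invalid panel for index construction."""


class ReliabilityWarning(UserWarning):
    """Raised (as a warning) when the index's internal consistency is low
    or not computable."""


@dataclass(frozen=True)
class AtiSeries:
    """The averaged index per week, with reliability metadata.

    ``alpha`` is Cronbach's alpha of the term panel the index was averaged
    from, or ``None`` when it is not computable (e.g. an all-constant panel).
    """

    week_start: tuple[dt.date, ...]
    values: np.ndarray
    n_terms: int
    alpha: float | None
    geo: str
    role: str

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if len(vals) != len(self.week_start):
            raise AtiIndexError("values and week axis length mismatch")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "week_start", tuple(self.week_start))
        if self.alpha is not None and self.alpha > 1.0 + 1e-12:
            raise AtiIndexError(f"alpha {self.alpha} exceeds 1")

    def __len__(self) -> int:
        return len(self.week_start)

    def to_csv(self, path: str | Path) -> None:
        """Write ``week,ati`` CSV plus a JSON metadata sidecar."""
        path = Path(path)
        lines = ["week,ati"]
        lines += [f"{w.isoformat()},{repr(float(v))}"
                  for w, v in zip(self.week_start, self.values)]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps({
            "n_terms": self.n_terms,
            "alpha": self.alpha,
            "geo": self.geo,
            "role": self.role,
            "n_weeks": len(self),
        }, indent=2), encoding="utf-8")


def cronbach_alpha(panel: TrendsPanel) -> float:
    """Cronbach's alpha: (k/(k-1)) * (1 - sum of item variances / total variance).

    Items are the panel's term series, observations are weeks; all variances
    use the sample (n-1 denominator) convention. Alpha may be negative for
    incoherent panels. An all-constant panel (zero total variance) is an
    error.
    """
    k = panel.n_terms
    if k < 2:
        raise AtiIndexError("alpha needs at least 2 terms")
    if panel.n_weeks < 3:
        raise AtiIndexError("alpha needs at least 3 weeks")
    mat = panel.values  # terms x weeks
    item_vars = mat.var(axis=1, ddof=1)
    total_var = mat.sum(axis=0).var(ddof=1)
    if total_var == 0.0:
        raise AtiIndexError("zero total variance: all-constant panel")
    return (k / (k - 1.0)) * (1.0 - item_vars.sum() / total_var)


def compute_ati(panel: TrendsPanel, min_alpha: float | None = None) -> AtiSeries:
    """Average a term panel into a weekly index on the 0–100 scale.

    Every term series — including accent-variant series, which enter as
    separate items — contributes with equal weight. When ``min_alpha`` is
    given and the panel's reliability falls below it (or alpha is not
    computable), a :class:`ReliabilityWarning` is emitted; the index is still
    returned.
    """
    if panel.n_terms == 0:
        raise AtiIndexError("empty panel")
    alpha: float | None
    try:
        alpha = cronbach_alpha(panel)
    except AtiIndexError as exc:
        alpha = None
        msg = f"reliability not computable ({exc}); alpha recorded as None"
        logger.warning(msg)
        warnings.warn(msg, ReliabilityWarning, stacklevel=2)
    if min_alpha is not None and alpha is not None and alpha < min_alpha:
        msg = (f"index reliability alpha={alpha:.3f} below the "
               f"min_alpha={min_alpha} threshold")
        logger.warning(msg)
        warnings.warn(msg, ReliabilityWarning, stacklevel=2)
    return AtiSeries(
        week_start=panel.week_start,
        values=panel.values.mean(axis=0),
        n_terms=panel.n_terms,
        alpha=alpha,
        geo=panel.geo,
        role=panel.role,
    )
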