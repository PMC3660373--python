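"""Empirical insert-size model and concordance cut-offs.

The insert length of a properly oriented pair is measured between the
innermost aligned positions, ``l = right - left``.  From the empirical
distribution of ``l`` over category-(1) pairs, an interval [LC, UC] is
taken at the alpha/2 and 1 - alpha/2 percentiles so that at least 1 - alpha
of a well-behaved library is called concordant.  For a normal library this
places UC at ``z_{1-alpha/2}`` standard deviations above the mean
(2.58 sigma at the default alpha = 0.01).

Percentiles use linear interpolation between order statistics
(``numpy.percentile`` default), which is deterministic and testable against
a sort-based oracle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Iterable, Optional, Sequence

import numpy as np

from .classify import Category, ReadPairRecord

DEFAULT_ALPHA = 0.01
#: subsample cap per library when estimating from a stream of pairs
DEFAULT_MAX_OBS = 1_000_000
#: below this many observations the model is flagged as unstable
DEFAULT_MIN_OBS = 1000


@dataclass
class InsertSizeModel:
    alpha: float
    LC: float
    UC: float
    median_l: float
    sd_l: float
    n_obs: int
    low_n_warning: bool = False

    @property
    def D(self) -> float:
        """Clustering distance bound UC - LC (equals ``2 z_{1-alpha/2} sigma``
        for a normal library)."""
        return self.UC - self.LC

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "InsertSizeModel":
        return cls(**d)


def insert_length(rp: ReadPairRecord) -> int:
    """Insert length of a category-(1)-oriented pair (leftmost read forward,
    rightmost reverse, same chromosome): distance between the innermost
    aligned positions.  May be negative when the reads overlap past each
    other; zero when they abut exactly.
    """
    a, b = rp.read_a, rp.read_b
    if not (a.mapped and b.mapped):
        raise ValueError("insert length needs both reads mapped")
    if a.chrom != b.chrom:
        raise ValueError("insert length undefined for inter-chromosomal pairs")
    if not (a.strand == "+" and b.strand == "-"):
        raise ValueError("insert length defined only for +/- ordered pairs")
    return b.start - a.end


def estimate_model(
    lengths: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
    min_obs: int = DEFAULT_MIN_OBS,
) -> InsertSizeModel:
    """Fit the empirical model: LC/UC at the alpha/2 and 1-alpha/2 percentiles."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot estimate insert model from zero lengths")
    lc, uc = np.percentile(arr, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    low_n = arr.size < min_obs
    if low_n:
        warnings.warn(
            f"insert model estimated from only {arr.size} pairs "
            f"(< {min_obs}); cut-offs may be unstable",
            stacklevel=2,
        )
    return InsertSizeModel(
        alpha=alpha,
        LC=float(lc),
        UC=float(uc),
        median_l=float(np.median(arr)),
        sd_l=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        n_obs=int(arr.size),
        low_n_warning=low_n,
    )


class ModelSet:
    """Per-library insert models keyed by read group (libraries in one run can
    have very different insert spreads).  A ``None`` key is the global
    fallback used for pairs without a read-group tag."""

    def __init__(self, models: dict):
        if not models:
            raise ValueError("empty model set")
        self.models = dict(models)
        self._default = self.models.get(None) or next(iter(self.models.values()))

    def for_pair(self, rp: ReadPairRecord) -> InsertSizeModel:
        return self.models.get(rp.read_group, self._default)

    @property
    def default(self) -> InsertSizeModel:
        return self._default

    def to_json(self) -> str:
        return json.dumps(
            {str(k): m.to_dict() for k, m in self.models.items()}, indent=2
        )


def estimate_from_pairs(
    pairs: Iterable[ReadPairRecord],
    alpha: float = DEFAULT_ALPHA,
    max_obs: int = DEFAULT_MAX_OBS,
    min_obs: int = DEFAULT_MIN_OBS,
) -> ModelSet:
    """Collect insert lengths from pairs in the category-(1) configuration
    (orientation/order only; no cut-offs exist yet) and fit one model per
    read group.  The first ``max_obs`` observations per library are used."""
    by_lib: dict = {}
    counts: dict = {}
    for rp in pairs:
        if rp.category in (Category.ONE_END, Category.ORPHAN):
            continue
        a, b = rp.read_a, rp.read_b
        if a.chrom != b.chrom or not (a.strand == "+" and b.strand == "-"):
            continue
        lib = rp.read_group
        n = counts.get(lib, 0)
        if n >= max_obs:
            continue
        by_lib.setdefault(lib, []).append(b.start - a.end)
        counts[lib] = n + 1
    if not by_lib:
        raise ValueError("no properly oriented pairs to estimate insert model")
    return ModelSet(
        {lib: estimate_model(ls, alpha=alpha, min_obs=min_obs) for lib, ls in by_lib.items()}
    )
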