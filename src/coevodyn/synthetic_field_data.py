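"""Synthetic site-by-year field parasitism observations.

The model-vs-field comparison stage needs site-level parasitism
proportions of the kind long-term monitoring programmes publish. No such
dataset ships with this package, so this module generates a synthetic
stand-in: site-level true rates drawn from a beta distribution around a
chosen mean (between-site overdispersion), observed through binomial
dissection counts. Beta-binomial is the minimal model of overdispersed
proportions; it carries no spatial or temporal autocorrelation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("coevodyn")

_COLUMNS = ["site", "year", "parasitism", "n"]


@dataclass
class FieldDataset:
    """Records of (site, year, observed parasitism proportion, sample size)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"field data missing columns: {missing}")
        self.validate()

    def validate(self) -> None:
        bad = self.frame.index[(self.frame["parasitism"] < 0)
                               | (self.frame["parasitism"] > 1)].tolist()
        if bad:
            raise ValueError(
                f"parasitism proportion out of [0, 1] in rows {bad}")
        bad = self.frame.index[self.frame["n"] < 1].tolist()
        if bad:
            raise ValueError(f"sample size < 1 in rows {bad}")

    @property
    def proportions(self) -> np.ndarray:
        return self.frame["parasitism"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, FieldDataset) and self.frame.equals(other.frame)


def generate_field_data(true_mean: float, dispersion: float, n_sites: int,
                        n_per_site: int, seed: int = 0,
                        year: int = 0) -> FieldDataset:
    """Beta-binomial site-level parasitism observations.

    Site-level true rates are beta-distributed with mean ``true_mean``
    and intraclass correlation ``dispersion`` (rho in (0, 1): the
    fraction of observed-proportion variance contributed by between-site
    spread; rho -> 0 collapses every site onto the mean). Observed
    proportions are binomial draws of ``n_per_site`` dissected hosts.
    """
    if not 0.0 <= true_mean <= 1.0:
        raise ValueError("true_mean must be in [0, 1]")
    if not 0.0 < dispersion < 1.0:
        raise ValueError("invalid dispersion: need 0 < rho < 1 for a "
                         "proper beta distribution")
    if n_sites < 1 or n_per_site < 1:
        raise ValueError("n_sites and n_per_site must be >= 1")
    rng = np.random.default_rng(seed)
    if true_mean in (0.0, 1.0):
        rates = np.full(n_sites, true_mean)
    else:
        conc = (1.0 - dispersion) / dispersion
        rates = rng.beta(true_mean * conc, (1.0 - true_mean) * conc, n_sites)
    counts = rng.binomial(n_per_site, rates)
    frame = pd.DataFrame({
        "site": [f"site_{i:03d}" for i in range(n_sites)],
        "year": year,
        "parasitism": counts / n_per_site,
        "n": n_per_site,
    })
    return FieldDataset(frame)


def write_field_csv(dataset: FieldDataset, path) -> None:
    dataset.frame.to_csv(path, index=False)


def read_field_csv(path) -> FieldDataset:
    """Read a (site, year, parasitism, n) CSV; malformed rows are named.

    An empty file yields an empty dataset with a warning.
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("empty field-data file %s", path)
        return FieldDataset(pd.DataFrame(columns=_COLUMNS))
    if frame.empty:
        logger.warning("field-data file %s has no rows", path)
    return FieldDataset(frame)
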