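"""Pluggable weight-for-age growth reference.

Weight-for-age SD scores are weight standardised against a reference mean
and SD indexed by postmenstrual age (gestation at birth plus postnatal age)
and sex.  The reference is injected as a table so any national growth
standard can be swapped in; the packaged default is a synthetic reference
(smooth, monotone in age, boys ~120 g heavier) used by the simulator and
the closed test loop.  It is NOT a published growth standard.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PMA_MIN, PMA_MAX = 34.0, 60.0


class GrowthReference:
    """Lookup of reference weight mean/SD by postmenstrual age (weeks) and sex.

    Built from a table with columns ``pma_weeks`` (integer grid), ``sex``
    (male/female), ``mean_g``, ``sd_g``; queries interpolate linearly in age
    and clip outside the tabulated range.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"pma_weeks", "sex", "mean_g", "sd_g"}
        if not required.issubset(table.columns):
            raise ValueError(f"growth reference table needs columns {sorted(required)}")
        self._grids: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for sex, sub in table.groupby("sex"):
            sub = sub.sort_values("pma_weeks")
            self._grids[str(sex)] = (
                sub["pma_weeks"].to_numpy(float),
                sub["mean_g"].to_numpy(float),
                sub["sd_g"].to_numpy(float),
            )

    def _interp(self, pma_weeks, sex, which: int) -> np.ndarray:
        pma = np.clip(np.asarray(pma_weeks, float), PMA_MIN, PMA_MAX)
        sex = np.asarray(sex, object)
        out = np.full(pma.shape, np.nan)
        for s, (grid, mean, sd) in self._grids.items():
            mask = sex == s
            if mask.any():
                out[mask] = np.interp(pma[mask], grid, (mean, sd)[which])
        return out

    def mean_g(self, pma_weeks, sex) -> np.ndarray:
        return self._interp(pma_weeks, sex, 0)

    def sd_g(self, pma_weeks, sex) -> np.ndarray:
        return self._interp(pma_weeks, sex, 1)

    def sd_score(self, weight_g, pma_weeks, sex) -> np.ndarray:
        """(weight - ref mean) / ref SD for the given age and sex."""
        w = np.asarray(weight_g, float)
        return (w - self.mean_g(pma_weeks, sex)) / self.sd_g(pma_weeks, sex)


def synthetic_reference() -> GrowthReference:
    """Synthetic default reference: ~3420/3300 g at 40 weeks, +130 g/week."""
    grid = np.arange(int(PMA_MIN), int(PMA_MAX) + 1, dtype=float)
    rows = []
    for sex, at40 in (("male", 3420.0), ("female", 3300.0)):
        mean = at40 + 130.0 * (grid - 40.0) - 1.5 * (grid - 40.0) ** 2 / 2.0
        sd = 450.0 + 12.0 * (grid - 40.0)
        rows.append(pd.DataFrame({"pma_weeks": grid, "sex": sex, "mean_g": mean, "sd_g": sd}))
    return GrowthReference(pd.concat(rows, ignore_index=True))
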