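"""Diversity and abundance indices of the station photo-quadrats.

Eight biotic responses are derived from the species-sediment cover matrix
(percent of the 0.16 m2 image covered by each of 12 biotic and 4 abiotic
variables, scored on a 100-square grid):

* species density ``d`` = richness / quadrat area (m^-2),
* overall abundance ``A`` = sum of biotic covers (%), and ``LogA``,
* Simpson diversity ``D`` = 1 - sum((a_i / A)^2), and ``LogD``,
* Shannon diversity ``H`` = -sum(f_i ln f_i) with f_i the *image fraction*
  (cover% / 100) of each present biotic variable, and ``LogH1`` =
  log10(H + 1),
* modified Pielou evenness ``mJ`` = H / ln(S + 1).

Note that ``H`` deliberately uses image fractions rather than proportions of
total abundance, so it is not scale-free: doubling all covers changes it.
Empty quadrats (A = 0) report D = H = mJ = 0 by convention.  Base-10 log
transforms floor their argument at 1e-4 so that zero-valued indices remain
finite and order-preserving.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from benthoscape.config import BIOTIC_POOL

#: The eight response columns, in fixed order.
RESPONSE_COLUMNS = ("d", "A", "LogA", "D", "LogD", "H", "LogH1", "mJ")

_LOG_FLOOR = 1e-4


def _log10(x: float) -> float:
    return float(np.log10(max(x, _LOG_FLOOR)))


def compute_indices(
    covers: pd.Series | dict,
    quadrat_area: float = 0.16,
    biotic_labels: tuple[str, ...] = BIOTIC_POOL,
) -> dict[str, float]:
    """Compute the eight biotic responses of one quadrat.

    ``covers`` maps variable names to percent cover; only the biotic labels
    enter the indices.  Raises on negative covers.
    """
    covers = pd.Series(covers, dtype=float)
    if (covers < 0).any():
        raise ValueError("covers must be non-negative")
    a = covers.reindex(list(biotic_labels), fill_value=0.0).to_numpy()
    present = a > 0
    S = int(present.sum())
    A = float(a.sum())
    if A > 0:
        p = a[present] / A
        D = float(1.0 - np.sum(p**2))
        f = a[present] / 100.0
        H = float(-np.sum(f * np.log(f)))
        mJ = H / np.log(S + 1)
    else:
        D = H = mJ = 0.0
    return {
        "S": S,
        "d": S / quadrat_area,
        "A": A,
        "LogA": _log10(A),
        "D": D,
        "LogD": _log10(D),
        "H": H,
        "LogH1": float(np.log10(H + 1.0)),
        "mJ": mJ,
    }


def index_table(
    quadrats: pd.DataFrame,
    quadrat_area: float = 0.16,
    biotic_labels: tuple[str, ...] = BIOTIC_POOL,
) -> pd.DataFrame:
    """One row of the eight responses per station, in input row order."""
    rows = [
        compute_indices(row, quadrat_area=quadrat_area, biotic_labels=biotic_labels)
        for _, row in quadrats.drop(columns=["station_id"], errors="ignore").iterrows()
    ]
    out = pd.DataFrame(rows)[["S", *RESPONSE_COLUMNS]]
    if "station_id" in quadrats:
        out.insert(0, "station_id", quadrats["station_id"].to_numpy())
    return out


def response_correlations(indices: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Pairwise Pearson and Spearman coefficients with two-sided p-values."""
    cols = [c for c in RESPONSE_COLUMNS if c in indices]
    n = len(cols)
    out = {}
    for name, fn in (("pearson", stats.pearsonr), ("spearman", stats.spearmanr)):
        r = np.eye(n)
        p = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                res = fn(indices[cols[i]], indices[cols[j]])
                r[i, j] = r[j, i] = res.statistic
                p[i, j] = p[j, i] = res.pvalue
        out[name] = pd.DataFrame(r, index=cols, columns=cols)
        out[f"{name}_p"] = pd.DataFrame(p, index=cols, columns=cols)
    return out
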