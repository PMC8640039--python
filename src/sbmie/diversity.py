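"""Alpha-diversity estimators for OTU count vectors.

Per sample: observed taxa S_obs, Shannon entropy (base 2 by default),
Gini-Simpson index 1 - sum p_i^2, the Chao1 and ACE richness estimators, and
Good's coverage 1 - F1/N, together with the intermediates they are built from
(F1 singletons, F2 doubletons, N reads).

Chao1 uses the classical estimator S_obs + F1^2 / (2 F2), falling back to
S_obs + F1 (F1 - 1) / 2 when there are no doubletons. ACE is the standard
abundance-based coverage estimator with rare threshold 10; with no rare taxa
ACE = S_obs, and in the degenerate case where every rare taxon is a singleton
(sample coverage of the rare fraction is zero) the Chao1 value is returned,
since the ACE ratio is undefined there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FeatureTable

__all__ = ["AlphaDiversity", "alpha_diversity", "alpha_diversity_table"]

RARE_THRESHOLD = 10


@dataclass
class AlphaDiversity:
    sample_id: str
    s_obs: int
    shannon: float
    simpson: float
    chao1: float
    ace: float
    goods_coverage: float
    f1: int
    f2: int
    n_reads: int


def alpha_diversity(counts, sample_id: str = "", base: float = 2.0) -> AlphaDiversity:
    """All alpha-diversity indices for one sample's count vector."""
    x = np.asarray(counts)
    if x.size == 0 or (x < 0).any():
        raise ValueError("counts must be a non-empty non-negative vector")
    if not np.issubdtype(x.dtype, np.integer):
        if not np.allclose(x, np.round(x)):
            raise ValueError("counts must be integers")
        x = np.round(x).astype(np.int64)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("at least one count must be positive")

    n = int(x.sum())
    s_obs = int(x.size)
    p = x / n
    shannon = float(-(p * (np.log(p) / np.log(base))).sum())
    simpson = float(1.0 - (p**2).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())

    if f2 > 0:
        chao1 = s_obs + f1**2 / (2.0 * f2)
    else:
        chao1 = s_obs + f1 * (f1 - 1) / 2.0

    rare = x[x <= RARE_THRESHOLD]
    s_rare, s_abund = int(rare.size), int(s_obs - rare.size)
    if s_rare == 0:
        ace = float(s_obs)
    else:
        n_rare = int(rare.sum())
        c_ace = 1.0 - f1 / n_rare
        if c_ace <= 0:
            ace = float(chao1)  # every rare taxon a singleton: ACE undefined
        else:
            i = np.arange(1, RARE_THRESHOLD + 1)
            fi = np.array([(rare == v).sum() for v in i])
            gamma2 = max(
                (s_rare / c_ace) * (i * (i - 1) * fi).sum() / (n_rare * (n_rare - 1)) - 1.0,
                0.0,
            ) if n_rare > 1 else 0.0
            ace = s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2

    goods = 1.0 - f1 / n
    return AlphaDiversity(
        sample_id=sample_id,
        s_obs=s_obs,
        shannon=shannon,
        simpson=simpson,
        chao1=float(chao1),
        ace=float(ace),
        goods_coverage=float(goods),
        f1=f1,
        f2=f2,
        n_reads=n,
    )


def alpha_diversity_table(table: FeatureTable, base: float = 2.0) -> pd.DataFrame:
    """Alpha diversity for every sample of an OTU count table."""
    rows = []
    for sid in table.sample_ids:
        div = alpha_diversity(table.data[sid].to_numpy(), sample_id=sid, base=base)
        rows.append(div.__dict__)
    return pd.DataFrame(rows).set_index("sample_id")
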