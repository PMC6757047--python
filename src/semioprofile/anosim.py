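"""ANOSIM with permutation nulls that respect repeated samples per female.

Whole-profile comparisons use Bray-Curtis dissimilarities on log(x+1)
relative peak areas.  The ANOSIM R statistic contrasts mean between-group
vs within-group dissimilarity ranks.  Because each female contributes many
samples, unrestricted label permutation is invalid; two restricted schemes
are provided:

``within_individual``
    Group labels are shuffled among the samples of each female,
    independently per female.  Appropriate for factors that vary within a
    female (cycle state).
``individual_level``
    The factor value of each female is permuted across females and
    propagated to all her samples.  Appropriate for factors constant within
    a female (age, parity), where within-individual shuffling would be a
    no-op and the test must instead exchange whole individuals.

P-values use the add-one convention p = (#{R_perm >= R_obs} + 1)/(n_perm + 1);
an exhaustive mode enumerates all distinct restricted relabellings for
small cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy.stats import rankdata

__all__ = ["AnosimResult", "bray_curtis", "anosim_statistic", "anosim_test"]

SCHEMES = ("within_individual", "individual_level")


@dataclass
class AnosimResult:
    R: float
    p: float
    n_perm: int
    scheme: str
    factor: str
    method: str = "montecarlo"

    def __str__(self) -> str:  # e.g. "ANOSIM, R = 0.32, P = 0.028"
        return f"ANOSIM ({self.factor}, {self.scheme}), R = {self.R:.2f}, P = {self.p:.3g}"


def bray_curtis(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix over sample rows.

    d(i,j) = sum|x_ik - x_jk| / sum(x_ik + x_jk); a pair of all-zero rows
    has d = 0 by convention.  Callers apply log(x+1) beforehand when
    working from relative areas.
    """
    X = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative inputs")
    with np.errstate(invalid="ignore"):
        d = pdist(X, metric="braycurtis")
    d = np.nan_to_num(d, nan=0.0)  # both-rows-zero pairs
    dm = squareform(d)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(dm, index=matrix.index, columns=matrix.index)
    return pd.DataFrame(dm)


def _condensed_ranks(dm: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = dm.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    ranks = rankdata(dm[iu, ju])  # average ranks for ties
    return ranks, iu, ju


def _r_from_ranks(ranks: np.ndarray, iu: np.ndarray, ju: np.ndarray, codes: np.ndarray) -> float:
    within = codes[iu] == codes[ju]
    if within.all() or not within.any():
        raise ValueError("ANOSIM requires both within- and between-group pairs")
    m = ranks.size
    return float((ranks[~within].mean() - ranks[within].mean()) / (m / 2.0))


def anosim_statistic(dis: pd.DataFrame | np.ndarray, groups: Sequence) -> float:
    """ANOSIM R = (mean between-group rank - mean within-group rank) / (M/2)."""
    dm = dis.to_numpy() if isinstance(dis, pd.DataFrame) else np.asarray(dis, float)
    codes = pd.factorize(np.asarray(groups))[0]
    if len(codes) != dm.shape[0]:
        raise ValueError("groups length must match the dissimilarity matrix")
    if len(set(codes)) < 2:
        raise ValueError("ANOSIM is undefined for a single group")
    ranks, iu, ju = _condensed_ranks(dm)
    return _r_from_ranks(ranks, iu, ju, codes)


def _distinct_perms(values: tuple) -> list[tuple]:
    return sorted(set(permutations(values)))


def anosim_test(
    dis: pd.DataFrame | np.ndarray,
    groups: Sequence,
    individuals: Sequence,
    scheme: str = "within_individual",
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "montecarlo",
    factor: str = "factor",
    max_exhaustive: int = 500_000,
) -> AnosimResult:
    """Restricted-permutation ANOSIM test.

    ``method='montecarlo'`` draws ``n_perm`` restricted relabellings and uses
    the add-one p-value; ``method='exhaustive'`` enumerates every distinct
    restricted relabelling (including the observed one) and reports the
    exact null proportion with R_perm >= R_obs.
    """
    dm = dis.to_numpy() if isinstance(dis, pd.DataFrame) else np.asarray(dis, float)
    g = np.asarray(groups)
    ind = np.asarray(individuals)
    if not (len(g) == len(ind) == dm.shape[0]):
        raise ValueError("groups/individuals must match the dissimilarity matrix")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")

    by_ind = {u: np.flatnonzero(ind == u) for u in pd.unique(ind)}
    if scheme == "within_individual":
        varies = [u for u, idx in by_ind.items() if len(set(g[idx])) > 1]
        if not varies:
            raise ValueError(
                f"factor {factor!r} is constant within every individual; "
                "within-individual permutation has no exchangeability — "
                "use scheme='individual_level'"
            )
    else:
        for u, idx in by_ind.items():
            if len(set(g[idx])) > 1:
                raise ValueError(
                    f"factor {factor!r} varies within individual {u!r}; "
                    "individual-level permutation requires it constant — "
                    "use scheme='within_individual'"
                )

    ranks, iu, ju = _condensed_ranks(dm)
    codes = pd.factorize(g)[0]
    r_obs = _r_from_ranks(ranks, iu, ju, codes)
    rng = np.random.default_rng(seed)

    def perm_codes_mc() -> np.ndarray:
        c = codes.copy()
        if scheme == "within_individual":
            for idx in by_ind.values():
                c[idx] = c[rng.permutation(idx)]
        else:
            us = list(by_ind)
            vals = [codes[by_ind[u][0]] for u in us]
            for u, v in zip(us, [vals[i] for i in rng.permutation(len(us))]):
                c[by_ind[u]] = v
        return c

    if method == "montecarlo":
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        n_ge = 0
        for _ in range(n_perm):
            try:
                r_p = _r_from_ranks(ranks, iu, ju, perm_codes_mc())
            except ValueError:  # degenerate relabelling (all one group on pairs)
                r_p = np.inf
            if r_p >= r_obs - 1e-12:
                n_ge += 1
        p = (n_ge + 1) / (n_perm + 1)
        return AnosimResult(r_obs, p, n_perm, scheme, factor, "montecarlo")

    if method != "exhaustive":
        raise ValueError(f"unknown method {method!r}")

    # enumerate all distinct restricted relabellings
    if scheme == "within_individual":
        blocks = [by_ind[u] for u in by_ind]
        per_block = [_distinct_perms(tuple(codes[idx])) for idx in blocks]
        total = int(np.prod([len(p_) for p_ in per_block]))
        if total > max_exhaustive:
            raise ValueError(f"exhaustive enumeration would need {total} relabellings")
        n_ge = 0
        count = 0

        def rec(i: int, c: np.ndarray) -> None:
            nonlocal n_ge, count
            if i == len(blocks):
                count += 1
                if _r_from_ranks(ranks, iu, ju, c) >= r_obs - 1e-12:
                    n_ge += 1
                return
            for pm in per_block[i]:
                c2 = c.copy()
                c2[blocks[i]] = pm
                rec(i + 1, c2)

        rec(0, codes.copy())
    else:
        us = list(by_ind)
        vals = tuple(codes[by_ind[u][0]] for u in us)
        if factorial(len(us)) > max_exhaustive:
            raise ValueError("exhaustive enumeration too large")
        n_ge = 0
        count = 0
        for pm in _distinct_perms(vals):
            c = codes.copy()
            for u, v in zip(us, pm):
                c[by_ind[u]] = v
            count += 1
            if _r_from_ranks(ranks, iu, ju, c) >= r_obs - 1e-12:
                n_ge += 1
    p = n_ge / count
    return AnosimResult(r_obs, p, count, scheme, factor, "exhaustive")
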