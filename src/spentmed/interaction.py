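"""Predicted competitive interactions from niche overlap.

The predicted interaction strength of influencer i on recipient r is the
directional overlap of their substrate-depletion profiles,

    PIS_ri = - sum_m p_{m,r} p_{m,i} / sum_m p_{m,r}^2,

a number in (-inf, 0]: 0 when the two isolates deplete disjoint substrate
sets (no competition predicted) and -1 when the influencer's profile matches
the recipient's exactly.  It is invariant to a common positive rescaling of
all profiles, so percentages and fractions give the same matrix.

The competitive rank of an isolate sums incoming minus outgoing predicted
effects over all other isolates,

    R_r = sum_i (PIS_ri - PIS_ir),

and therefore sums to zero over the community; larger R_r means a greater
potential to engage in competitive interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PISMatrix:
    """Directional predicted interaction strengths, recipients x influencers.

    ``values[r, i]`` is the predicted strength of influencer i on recipient
    r.  The diagonal is NaN; rows for recipients with an empty depletion
    support are NaN and listed in ``undefined_recipients`` (the defining
    ratio is 0/0 for them).
    """

    values: pd.DataFrame
    undefined_recipients: list[str] = field(default_factory=list)

    @property
    def isolates(self) -> list[str]:
        return list(self.values.index)


def predicted_interactions(profiles: pd.DataFrame) -> PISMatrix:
    """PIS matrix from a metabolites x isolates depletion-fraction matrix."""
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 isolate profiles")
    if profiles.isna().to_numpy().any():
        raise ValueError("profiles contain missing values")
    P = profiles.to_numpy(dtype=float)  # M x I
    if (P < 0).any():
        raise ValueError("depletion fractions must be non-negative")
    isolates = list(profiles.columns)
    denom = (P**2).sum(axis=0)  # per recipient
    overlap = P.T @ P  # I x I, overlap[r, i] = sum_m p_mr p_mi
    if (denom == 0).all():
        raise ValueError("all profiles have empty support")
    with np.errstate(divide="ignore", invalid="ignore"):
        pis = -overlap / denom[:, None]
    pis[denom == 0, :] = np.nan
    np.fill_diagonal(pis, np.nan)
    values = pd.DataFrame(pis, index=isolates, columns=isolates)
    undefined = [iso for iso, d in zip(isolates, denom) if d == 0]
    return PISMatrix(values, undefined)


def competitive_rank(pis: PISMatrix) -> pd.DataFrame:
    """Competitive ranks R_r and their ordering (rank 1 = largest R).

    Recipients flagged undefined are excluded from the ranking.
    """
    keep = [iso for iso in pis.isolates if iso not in pis.undefined_recipients]
    if len(keep) < 2:
        raise ValueError("fewer than 2 isolates with defined profiles")
    V = pis.values.loc[keep, keep].to_numpy(dtype=float)
    V = np.where(np.isnan(V), 0.0, V)  # diagonal only; off-diagonals are defined
    R = V.sum(axis=1) - V.sum(axis=0)
    out = pd.DataFrame({"R": R}, index=pd.Index(keep, name="isolate"))
    out["rank"] = out["R"].rank(ascending=False, method="min").astype(int)
    return out.sort_values("rank")


def cluster_order(pis: PISMatrix) -> list[str]:
    """Average-linkage (Euclidean) leaf order of the PIS rows.

    Presentation aid for heatmaps only; no analysis depends on it.
    """
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import pdist

    keep = [iso for iso in pis.isolates if iso not in pis.undefined_recipients]
    M = pis.values.loc[keep, keep].fillna(0.0).to_numpy()
    if len(keep) < 3:
        return keep
    Z = hierarchy.linkage(pdist(M), method="average")
    return [keep[k] for k in hierarchy.leaves_list(Z)]
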