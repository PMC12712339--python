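"""Directional pathway over-representation analysis (ORA).

A selected feature set is tested against each pathway with the upper-tail
hypergeometric probability P(X >= k) of drawing k pathway members in n
selections from a universe of N features containing K members. Directional
mode tests the up- and down-regulated selections separately so a pathway
can score with a sign: positive for increased abundance in quiescence,
negative for decreased.

The universe defaults to the features of the analyzed matrix that belong to
at least one pathway set — ORA p-values are sensitive to this choice, so it
is explicit and configurable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .diffstats import bh_adjust
from .io import GeneSetCollection

ENRICHMENT_COLUMNS = [
    "pathway_id", "name", "direction", "k", "K", "n", "N",
    "p", "fdr", "signed_score", "significant",
]


def ora(
    selected: set[str],
    universe: set[str],
    sets: GeneSetCollection,
    direction: str = "association",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` within ``universe``.

    Pathway sets are intersected with the universe; sets with no members in
    the universe are skipped. BH correction runs across the tested pathways.
    """
    selected = set(selected)
    universe = set(universe)
    if not selected <= universe:
        extra = sorted(selected - universe)[:3]
        raise ConfigurationError(f"selected features outside universe, e.g. {extra}")
    restricted = sets.restrict_to(universe)
    N, n = len(universe), len(selected)
    rows = []
    for pid in restricted:
        members = restricted.members[pid]
        K = len(members)
        k = len(members & selected)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"pathway_id": pid, "name": restricted.names[pid],
                     "direction": direction, "k": k, "K": K, "n": n, "N": N,
                     "p": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:8])
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
    else:
        out["fdr"] = pd.Series(dtype=float)
    sign = -1.0 if direction == "down_in_quiescence" else 1.0
    with np.errstate(divide="ignore"):
        out["signed_score"] = sign * (-np.log10(out["fdr"].to_numpy(dtype=float)
                                                if len(out) else np.array([])))
    out["significant"] = out["fdr"] < alpha
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def directional_enrichment(
    records: pd.DataFrame,
    sets: GeneSetCollection,
    mode: str = "protein",
    universe: set[str] | None = None,
    alpha: float = 0.05,
    pool_directions: bool = False,
) -> pd.DataFrame:
    """ORA of up- and down-regulated features, tested separately per direction.

    ``protein`` mode selects by Storey q < 0.05 and |log2fc| > 0.5;
    ``metabolite`` mode selects by raw p < 0.05 and |log2fc| > 0.25 and calls
    a pathway significant at BH-adjusted enrichment p < 0.05. All
    inequalities are strict. By default BH runs within each direction
    (``pool_directions`` pools both into one correction).
    """
    if mode == "protein":
        fc_cutoff, score_col, score_alpha = 0.5, "q", 0.05
    elif mode == "metabolite":
        fc_cutoff, score_col, score_alpha = 0.25, "p", 0.05
    else:
        raise ConfigurationError(f"unknown mode {mode!r}; use protein|metabolite")
    if score_col not in records.columns:
        raise ConfigurationError(f"records lack required column {score_col!r}")

    if universe is None:
        in_any_set = set().union(*sets.members.values()) if len(sets) else set()
        universe = set(records.index) & in_any_set
    meets_p = records[score_col] < score_alpha
    up = set(records.index[meets_p & (records["log2fc"] > fc_cutoff)]) & universe
    down = set(records.index[meets_p & (records["log2fc"] < -fc_cutoff)]) & universe

    parts = []
    for selection, direction in ((up, "up_in_quiescence"), (down, "down_in_quiescence")):
        if selection:  # an empty selection yields no records for its direction
            parts.append(ora(selection, universe, sets, direction=direction, alpha=alpha))
    if not parts:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    out = pd.concat(parts, ignore_index=True)
    if pool_directions and len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
        sign = np.where(out["direction"] == "down_in_quiescence", -1.0, 1.0)
        with np.errstate(divide="ignore"):
            out["signed_score"] = sign * -np.log10(out["fdr"].to_numpy(dtype=float))
        out["significant"] = out["fdr"] < alpha
    return out
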