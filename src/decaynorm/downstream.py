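"""Downstream reporting: top-N over-representation analysis, marker-panel
fold-change reports across comparisons, and the comparative-Ct helper."""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .detest import bh_adjust

log = logging.getLogger(__name__)

TOP_N_DEFAULTS = (50, 100, 250, 500, 1000)


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a testing universe."""

    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def restricted(self) -> dict[str, set[str]]:
        out = {}
        for name, members in self.sets.items():
            inter = members & self.universe if self.universe else set(members)
            if not inter:
                log.info("gene set %s has no overlap with the universe; skipped", name)
                continue
            out[name] = inter
        return out


def read_gmt(path: str) -> dict[str, set[str]]:
    """Read a GMT file (set name, description, members...) into a dict."""
    import gseapy

    return {name: set(members) for name, members in gseapy.read_gmt(path).items()}


def top_n_lists(table: pd.DataFrame, n: int, direction: str) -> list[str]:
    """Top *n* up- or down-regulated genes ranked by ascending p-value.

    Ties in p are broken by |logFC| descending, then by gene id, so lists
    are deterministic across runs.  If fewer than *n* genes carry the
    requested sign, all of them are returned with a warning.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    signed = table[table["logFC"] > 0] if direction == "up" else \
        table[table["logFC"] < 0]
    if len(signed) < n:
        warnings.warn(f"only {len(signed)} {direction}-regulated genes available "
                      f"(requested {n})")
    ranked = signed.assign(_abs=signed["logFC"].abs(),
                           _g=signed.index.astype(str)) \
        .sort_values(["p", "_abs", "_g"], ascending=[True, False, True],
                     kind="mergesort")
    return list(ranked.index[:n])


def hypergeom_enrichment(
    gene_list: list[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of *gene_list* in each
    set of *collection*, BH-adjusted across sets.

    p = P(X >= k) with population N = |universe|, K = |set|, draws
    n = |list|; the list must be a subset of the universe.
    """
    if not gene_list:
        raise ValueError("empty gene list")
    universe = collection.universe
    listed = set(gene_list)
    if not listed <= universe:
        raise ValueError("gene list is not a subset of the universe")
    N, n = len(universe), len(listed)
    rows = []
    for name, members in collection.restricted().items():
        K = len(members)
        k = len(members & listed)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((name, K, k, p))
    df = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df = df.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    return df


def marker_panel_report(
    tables: dict[str, pd.DataFrame],
    markers: list[str],
) -> pd.DataFrame:
    """logFC (and pass flag) of each marker gene in each comparison.

    Markers absent from a comparison's table are reported as not detected
    (NaN logFC, detected=False)."""
    rows = []
    for m in markers:
        row: dict[str, object] = {"marker": m}
        for comp, tab in tables.items():
            if m in tab.index:
                row[f"{comp}_logFC"] = float(tab.loc[m, "logFC"])
                row[f"{comp}_passed"] = bool(tab.loc[m, "passed"])
                row[f"{comp}_detected"] = True
            else:
                row[f"{comp}_logFC"] = np.nan
                row[f"{comp}_passed"] = False
                row[f"{comp}_detected"] = False
        rows.append(row)
    return pd.DataFrame(rows).set_index("marker")


def ddct(ct_target_trt: float, ct_ref_trt: float,
         ct_target_ctl: float, ct_ref_ctl: float) -> float:
    """Comparative-Ct relative quantity, RQ = 2^-ddCt.

    ddCt = (Ct_target - Ct_reference) in the treated condition minus the
    same difference in the control; amplification efficiency is fixed at 2.
    """
    for ct in (ct_target_trt, ct_ref_trt, ct_target_ctl, ct_ref_ctl):
        if not np.isfinite(ct) or ct <= 0:
            raise ValueError("Ct values must be finite and positive")
    ddct_val = (ct_target_trt - ct_ref_trt) - (ct_target_ctl - ct_ref_ctl)
    return float(2.0 ** (-ddct_val))
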