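"""State-dependent hydrogen-bond network isolation and interface statistics.

The allosterically informative h-bonds of a PTP ensemble are isolated in
five steps:

1. detect h-bonds per frame (``interactions.detect_hbonds``) and aggregate
   per-trajectory occupancies;
2. remove *ubiquitous* bonds — formed in a majority of all trajectories
   regardless of ensemble — and bonds between sequence-adjacent residues
   (|Δindex| ≤ 3 within the chain);
3. compute each remaining bond's mean occupancy in the apo WPD-open and
   apo WPD-closed ensembles;
4. test the group difference per bond with Welch's unequal-variance
   t-test at the per-trajectory level (frames are autocorrelated;
   trajectories are the statistical unit);
5. assign each bond to the state where it appears more, provided
   p < α (default 0.01) and its mean occupancy in that primary state is at
   least 70%.

The assigned bonds form an undirected residue graph whose connectivity
verdict asks whether the active site (WPD + P loops) is linked to the
allosteric site (L-11, α3, α6, α7). Interface disruption statistics
compare interaction occupancies between ligand-bound and apo ensembles
with a one-sided Welch test (disruption = significant decrease).

No multiple-testing correction is applied by default, matching common
practice for these per-bond screens; Benjamini-Hochberg is available and
its use is logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .interactions import LIGAND, OccupancyTable
from .regions import RegionMap

__all__ = [
    "NetworkConfig", "WelchResult", "welch_ttest", "filter_ubiquitous",
    "filter_adjacent", "assign_state_bonds", "build_graph",
    "interface_disruption", "InterfaceReport", "NetworkResult",
    "DEFAULT_INTERFACES",
]

logger = logging.getLogger(__name__)

APO_OPEN, APO_CLOSED = "apo-open", "apo-closed"

#: the four allosteric interfaces reported for PTP catalytic domains
DEFAULT_INTERFACES = (("a3", "a7"), ("l11", "a7"), ("a3", "a6"), ("a6", "a7"))


@dataclass
class NetworkConfig:
    ubiquity_occupancy: float = 0.5     # "formed" within one trajectory
    ubiquity_fraction: float = 0.5      # fraction of all trajectories
    adjacency_window: int = 3           # |residue index difference| <= w
    alpha_network: float = 0.01         # two-sided, network membership
    min_primary_occupancy: float = 0.70
    alpha_disrupt: float = 0.05         # one-sided, interface disruption
    presence_threshold: float = 0.5     # interface interaction "present"
    fdr: bool = False                   # Benjamini-Hochberg on network p's

    def __post_init__(self):
        for a in (self.alpha_network, self.alpha_disrupt):
            if not 0.0 < a < 1.0:
                raise ValueError("significance levels must lie in (0, 1)")
        if not 0.0 < self.min_primary_occupancy <= 1.0:
            raise ValueError("min_primary_occupancy must lie in (0, 1]")


# ---------------------------------------------------------------- Welch

@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_ttest(x, y, alternative: str = "two-sided") -> WelchResult:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df.

    Conventions for degenerate inputs: identical zero-variance groups give
    p = 1 (no evidence of difference); zero variance with different means
    gives t = ±inf and the appropriate one/two-sided p.
    ``alternative='less'`` tests mean(x) < mean(y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx_, ny_ = len(x), len(y)
    if nx_ < 2 or ny_ < 2:
        raise ValueError("Welch's t-test needs at least 2 samples per group")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx_ + vy / ny_
    if se2 == 0.0:
        if mx == my:
            return WelchResult(0.0, float(nx_ + ny_ - 2), 1.0)
        t = math.inf if mx > my else -math.inf
        df = float(nx_ + ny_ - 2)
    else:
        t = (mx - my) / math.sqrt(se2)
        df = se2 ** 2 / (vx ** 2 / (nx_ ** 2 * (nx_ - 1))
                         + vy ** 2 / (ny_ ** 2 * (ny_ - 1)))
    if alternative == "two-sided":
        p = 2.0 * float(stats.t.sf(abs(t), df))
    elif alternative == "less":
        p = float(stats.t.cdf(t, df))
    elif alternative == "greater":
        p = float(stats.t.sf(t, df))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return WelchResult(float(t), float(df), min(p, 1.0))


# ---------------------------------------------------------------- filters

def filter_ubiquitous(table: OccupancyTable,
                      cfg: NetworkConfig | None = None) -> OccupancyTable:
    """Drop interactions formed in a majority of *all* trajectories,
    regardless of ensemble label: occupancy > ``ubiquity_occupancy`` in
    strictly more than ``ubiquity_fraction`` of trajectories."""
    cfg = cfg or NetworkConfig()
    if table.data.empty:
        return table
    formed = (table.data > cfg.ubiquity_occupancy).sum(axis=1)
    n = table.data.shape[1]
    keep = formed <= cfg.ubiquity_fraction * n
    return table.subset(table.data.index[keep])


def filter_adjacent(table: OccupancyTable,
                    cfg: NetworkConfig | None = None) -> OccupancyTable:
    """Drop bonds between sequence-adjacent residues (|Δindex| ≤ window).
    Pairs involving the ligand are retained: sequence adjacency is
    undefined across chains."""
    cfg = cfg or NetworkConfig()
    keep = []
    for key in table.data.index:
        rec = table.records[key]
        a, b = rec.residue_pair()
        if isinstance(a, int) and isinstance(b, int) \
                and abs(a - b) <= cfg.adjacency_window:
            continue
        keep.append(key)
    return table.subset(keep)


# ---------------------------------------------------------------- network

@dataclass
class NetworkResult:
    bonds: pd.DataFrame          # per-bond statistics and assigned state
    graph: nx.Graph | None = None
    connected: bool | None = None
    records: dict = field(default_factory=dict)

    def assigned(self, state: str) -> list[str]:
        sel = self.bonds[self.bonds["state"] == state]
        return list(sel.index)


def assign_state_bonds(table: OccupancyTable,
                       cfg: NetworkConfig | None = None) -> NetworkResult:
    """Steps (iii)-(v): per-bond Welch test apo-open vs apo-closed and
    state assignment.

    A bond is assigned to its higher-mean state iff the two-sided p-value
    is below ``alpha_network`` *and* its mean occupancy in that state is
    at least ``min_primary_occupancy``; otherwise its state is ``none``.
    """
    cfg = cfg or NetworkConfig()
    open_cols = table.columns_with_label(APO_OPEN)
    closed_cols = table.columns_with_label(APO_CLOSED)
    if len(open_cols) < 2 or len(closed_cols) < 2:
        raise ValueError("need >= 2 apo-open and >= 2 apo-closed trajectories")
    rows = []
    for key in table.data.index:
        xo = table.data.loc[key, open_cols].to_numpy(dtype=float)
        xc = table.data.loc[key, closed_cols].to_numpy(dtype=float)
        res = welch_ttest(xo, xc, alternative="two-sided")
        rows.append({"bond": key, "mean_open": xo.mean(),
                     "mean_closed": xc.mean(), "t": res.t, "df": res.df,
                     "p": res.p})
    df = pd.DataFrame(rows).set_index("bond") if rows else pd.DataFrame(
        columns=["mean_open", "mean_closed", "t", "df", "p"])
    pcol = df["p"].to_numpy(dtype=float) if len(df) else np.array([])
    if cfg.fdr and len(df):
        from statsmodels.stats.multitest import multipletests
        pcol = multipletests(pcol, method="fdr_bh")[1]
        logger.warning("Benjamini-Hochberg correction applied to %d network "
                       "p-values (off by default)", len(pcol))
    df["p_eff"] = pcol
    states = []
    for key, row in df.iterrows():
        primary = "open-network" if row["mean_open"] > row["mean_closed"] \
            else "closed-network"
        pmean = max(row["mean_open"], row["mean_closed"])
        if row["p_eff"] < cfg.alpha_network and \
                pmean >= cfg.min_primary_occupancy and \
                row["mean_open"] != row["mean_closed"]:
            states.append(primary)
        else:
            states.append("none")
    df["state"] = states
    return NetworkResult(bonds=df, records=dict(table.records))


def build_graph(result: NetworkResult, regions: RegionMap,
                state: str = "closed-network") -> NetworkResult:
    """Build the residue graph of assigned bonds of one state and decide
    connectivity between the active site (WPD + P loop) and the
    allosteric site (L-11, α3, α6, α7)."""
    g = nx.Graph()
    for key in result.assigned(state):
        rec = result.records[key]
        a, b = rec.residue_pair()
        g.add_edge(a, b, bond=key)
    active = regions.active_site_residues()
    allo = regions.allosteric_site_residues()
    connected = False
    for s in active & set(g.nodes):
        if connected:
            break
        seen = nx.descendants(g, s) | {s}
        if seen & allo:
            connected = True
    result.graph = g
    result.connected = connected
    return result


# ---------------------------------------------------------------- interfaces

@dataclass
class InterfaceReport:
    interface: tuple[str, str]
    counts: dict[str, int]               # ensemble label -> #present
    percent_difference: float            # closed vs open, (c-o)/o * 100
    undefined_percent: bool
    disrupted: pd.DataFrame              # per ligand ensemble, p < alpha


def interface_disruption(table: OccupancyTable, regions: RegionMap,
                         interface: tuple[str, str],
                         cfg: NetworkConfig | None = None,
                         baseline: str = APO_CLOSED,
                         strict_groups: bool = True) -> InterfaceReport:
    """Interface interaction counts per ensemble and the ligand-disruption
    test.

    An interaction is *present* in an ensemble iff its mean occupancy over
    that ensemble's trajectories exceeds ``presence_threshold``. The
    percent difference reports closed relative to open:
    ``(n_closed - n_open) / n_open * 100`` (0 with a flag when no
    interaction is present in the open state). An interaction is
    *disrupted* by a ligand iff it occurs significantly less
    (one-sided Welch, p < ``alpha_disrupt``) in that ligand ensemble than
    in ``baseline``.
    """
    cfg = cfg or NetworkConfig()
    ra, rb = interface
    res_a = set(regions.residues(ra))
    res_b = set(regions.residues(rb))
    keys = []
    for key in table.data.index:
        a, b = table.records[key].residue_pair()
        if a == LIGAND or b == LIGAND:
            continue
        if (a in res_a and b in res_b) or (a in res_b and b in res_a):
            keys.append(key)
    sub = table.subset(keys)
    ensembles = sorted(set(table.labels.values()))
    counts = {}
    for label in ensembles:
        cols = sub.columns_with_label(label)
        if not cols:
            continue
        mean_occ = sub.data[cols].mean(axis=1)
        counts[label] = int((mean_occ > cfg.presence_threshold).sum())
    n_open = counts.get(APO_OPEN, 0)
    n_closed = counts.get(APO_CLOSED, 0)
    if n_open > 0:
        pct, undef = (n_closed - n_open) / n_open * 100.0, False
    else:
        pct, undef = 0.0, True
    base_cols = sub.columns_with_label(baseline)
    rows = []
    for label in ensembles:
        if not label.startswith("ligand"):
            continue
        lig_cols = sub.columns_with_label(label)
        if len(lig_cols) < 2 or len(base_cols) < 2:
            if strict_groups:
                raise ValueError(f"group sizes < 2 for disruption test "
                                 f"({label} vs {baseline})")
            logger.warning("skipping disruption test %s vs %s: group < 2",
                           label, baseline)
            continue
        for key in sub.data.index:
            xl = sub.data.loc[key, lig_cols].to_numpy(dtype=float)
            xb = sub.data.loc[key, base_cols].to_numpy(dtype=float)
            res = welch_ttest(xl, xb, alternative="less")
            if res.p < cfg.alpha_disrupt:
                rows.append({"ensemble": label, "interaction": key,
                             "t": res.t, "df": res.df, "p": res.p})
    disrupted = pd.DataFrame(rows, columns=["ensemble", "interaction",
                                            "t", "df", "p"])
    return InterfaceReport(interface=interface, counts=counts,
                           percent_difference=pct, undefined_percent=undef,
                           disrupted=disrupted)
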