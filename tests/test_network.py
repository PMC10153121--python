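"""Network isolation: filters, Welch statistics, graph, interfaces."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from allonet.interactions import InteractionRecord, OccupancyTable
from allonet.network import (NetworkConfig, assign_state_bonds, build_graph,
                             filter_adjacent, filter_ubiquitous,
                             interface_disruption, welch_ttest)
from allonet.regions import RegionMap

CFG = NetworkConfig()


def make_table(rows, labels):
    """rows: {key_or_record: [occupancies per trajectory]}"""
    records, data = {}, {}
    for rec, occ in rows.items():
        if isinstance(rec, tuple):
            rec = InteractionRecord("hbond", rec[0], rec[1], ("N", "H", "O"))
        records[rec.key] = rec
        data[rec.key] = occ
    names = [f"t{i}" for i in range(len(next(iter(rows.values()))))]
    df = pd.DataFrame(data, index=names).T
    return OccupancyTable(df, records, dict(zip(names, labels)))


LBL8 = ["apo-open"] * 4 + ["apo-closed"] * 4


# --------------------------------------------------------------- Welch

def test_welch_matches_textbook_formulas_to_1e10():
    cases = [
        ([0.10, 0.15, 0.08, 0.12], [0.92, 0.88, 0.95, 0.90]),
        ([1.0, 2.0, 3.0, 4.0, 5.0], [2.0, 2.1, 1.9, 2.05]),
        ([0.5, 0.6, 0.7], [0.1, 0.9, 0.4, 0.3, 0.6]),
    ]
    for x, y in cases:
        got = welch_ttest(x, y)
        t, df, p = oracles.welch_reference(x, y)
        assert abs(got.t - t) < 1e-10
        assert abs(got.df - df) < 1e-10
        assert abs(got.p - p) < 1e-10


@given(st.lists(st.floats(0, 1, width=32), min_size=2, max_size=8),
       st.lists(st.floats(0, 1, width=32), min_size=2, max_size=8))
@settings(max_examples=100, deadline=None)
def test_welch_agrees_with_scipy(x, y):
    from scipy.stats import ttest_ind
    got = welch_ttest(x, y)
    if np.var(x) + np.var(y) == 0:
        assert got.p == 1.0 if np.mean(x) == np.mean(y) else got.p == 0.0
    else:
        ref = ttest_ind(x, y, equal_var=False)
        assert got.t == pytest.approx(ref.statistic, abs=1e-10)
        assert got.p == pytest.approx(ref.pvalue, abs=1e-10)


def test_welch_degenerate_conventions():
    assert welch_ttest([0.5, 0.5], [0.5, 0.5]).p == 1.0
    r = welch_ttest([1.0, 1.0], [0.0, 0.0])
    assert r.t == np.inf and r.p == 0.0
    with pytest.raises(ValueError):
        welch_ttest([1.0], [0.0, 0.0])


# --------------------------------------------------------------- filters

def test_ubiquitous_bond_removed_state_bond_kept():
    table = make_table({
        (10, 40): [0.95] * 8,                      # ubiquitous everywhere
        (11, 41): [0.1] * 4 + [0.9] * 4,           # closed-specific (half)
    }, LBL8)
    out = filter_ubiquitous(table, CFG)
    assert list(out.data.index) == ["hbond:11:41:N/H/O"]


def test_empty_table_passes_filters():
    table = make_table({(1, 9): [0.0] * 4}, ["apo-open"] * 4)
    empty = table.subset([])
    assert filter_ubiquitous(empty, CFG).data.empty
    assert filter_adjacent(empty, CFG).data.empty


def test_adjacent_bonds_dropped_ligand_pairs_kept():
    lig = InteractionRecord("hbond", 185, "ligand", ("N", "H", "O1"))
    table = make_table({
        (185, 187): [0.9] * 8,         # |Δ| = 2 -> dropped
        (185, 189): [0.9] * 8,         # |Δ| = 4 -> kept
        lig: [0.9] * 8,                # cross-chain -> kept
    }, LBL8)
    out = filter_adjacent(table, CFG)
    assert set(out.data.index) == {"hbond:185:189:N/H/O",
                                   "hbond:185:ligand:N/H/O1"}


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=20, deadline=None)
def test_filter_order_independence(seed):
    rng = np.random.default_rng(seed)
    rows = {}
    for k in range(30):
        a = int(rng.integers(0, 80))
        b = int(rng.integers(0, 80))
        if a == b:
            continue
        rows[(a, b + 100) if (a, b) in rows else (a, b)] = \
            list(rng.random(8).round(2))
    if not rows:
        return
    table = make_table(rows, LBL8)
    ab = filter_adjacent(filter_ubiquitous(table, CFG), CFG)
    ba = filter_ubiquitous(filter_adjacent(table, CFG), CFG)
    assert list(ab.data.index) == list(ba.data.index)


# --------------------------------------------------------------- assignment

def test_assignment_example_with_welch_oracle():
    closed = [0.92, 0.88, 0.95, 0.90]
    opened = [0.10, 0.15, 0.08, 0.12]
    table = make_table({(10, 40): opened + closed}, LBL8)
    res = assign_state_bonds(table, CFG)
    row = res.bonds.iloc[0]
    t, df, p = oracles.welch_reference(opened, closed)
    assert row["state"] == "closed-network"
    assert row["t"] == pytest.approx(t, abs=1e-10)
    assert row["p"] == pytest.approx(p, abs=1e-10)


def test_seventy_percent_floor_blocks_assignment():
    table = make_table({(10, 40): [0.10, 0.12, 0.11, 0.09,
                                   0.60, 0.61, 0.59, 0.60]}, LBL8)
    res = assign_state_bonds(table, CFG)
    assert res.bonds.iloc[0]["p"] < 0.01        # significant...
    assert res.bonds.iloc[0]["state"] == "none"  # ...but below the floor


def test_identical_groups_unassigned_p_one():
    table = make_table({(10, 40): [0.8] * 8}, LBL8)
    res = assign_state_bonds(table, CFG)
    assert res.bonds.iloc[0]["p"] == 1.0
    assert res.bonds.iloc[0]["state"] == "none"


def test_two_trajectories_per_group_required():
    table = make_table({(10, 40): [0.9, 0.1, 0.2, 0.3]},
                       ["apo-open", "apo-closed", "apo-closed", "apo-closed"])
    with pytest.raises(ValueError, match=">= 2"):
        assign_state_bonds(table, CFG)


def test_null_calibration_at_table_level():
    """Equal planted occupancies in both states (0.75, above the primary
    floor so the p-value is the operative criterion): the fraction of
    state-assigned bonds stays within 3 binomial SDs of alpha."""
    n_bonds, n_seeds = 100, 20
    assigned = total = 0
    for seed in range(n_seeds):
        rng = np.random.default_rng(10_000 + seed)
        occ = rng.binomial(300, 0.75, size=(n_bonds, 8)) / 300.0
        rows = {(i, i + 200): list(occ[i]) for i in range(n_bonds)}
        res = assign_state_bonds(make_table(rows, LBL8), CFG)
        assigned += int((res.bonds["state"] != "none").sum())
        total += n_bonds
    rate = assigned / total
    bound = 0.01 + 3 * np.sqrt(0.01 * 0.99 / total)
    assert rate <= bound


# --------------------------------------------------------------- graph

def _regions():
    return RegionMap(regions={"wpd": (8, 16), "ploop": (20, 28),
                              "l11": (32, 38), "a3": (42, 52),
                              "a6": (56, 64), "a7": (87, 98)},
                     catalytic_acid=12, nucleophile=24)


def test_planted_path_connects_active_to_allosteric():
    # chain WPD -> L-11 -> α3 -> α7, all strongly closed-specific
    chain = [(10, 33), (33, 45), (45, 90)]
    rows = {p: [0.05, 0.04, 0.06, 0.05, 0.92, 0.91, 0.93, 0.90]
            for p in chain}
    res = assign_state_bonds(make_table(rows, LBL8), CFG)
    res = build_graph(res, _regions(), state="closed-network")
    assert res.connected
    edges = list(res.graph.edges)
    assert oracles.bfs_reachable(edges, set(range(8, 28)),
                                 set(range(32, 98)))


def test_no_assigned_bonds_graph_empty_verdict_false():
    rows = {(10, 33): [0.5] * 8}
    res = build_graph(assign_state_bonds(make_table(rows, LBL8), CFG),
                      _regions())
    assert not res.connected and res.graph.number_of_edges() == 0


def test_disconnected_components_verdict_false():
    # one edge inside the active site, one inside the allosteric site
    rows = {p: [0.05, 0.04, 0.06, 0.05, 0.92, 0.91, 0.93, 0.90]
            for p in [(10, 22), (33, 45)]}
    res = build_graph(assign_state_bonds(make_table(rows, LBL8), CFG),
                      _regions())
    assert res.graph.number_of_edges() == 2
    assert not res.connected


# --------------------------------------------------------------- interfaces

LBL12 = LBL8 + ["ligand:AD"] * 4


def _iface_record(a, b):
    return InteractionRecord("contact", a, b)


def test_interface_disruption_and_percent_difference():
    rows = {}
    # 20 interactions present when closed, 16 when open -> +25%
    for k in range(20):
        a, b = 42 + (k % 10), 87 + (k % 11)
        rec = InteractionRecord("contact", a, b, (f"i{k}",))
        closed_occ = [0.9, 0.92, 0.88, 0.91]
        open_occ = [0.8] * 4 if k < 16 else [0.1] * 4
        lig_occ = [0.08, 0.12, 0.10, 0.11] if k == 0 else closed_occ
        rows[rec] = open_occ + closed_occ + lig_occ
    table = make_table(rows, LBL12)
    rep = interface_disruption(table, _regions(), ("a3", "a7"), CFG)
    assert rep.counts["apo-closed"] == 20
    assert rep.counts["apo-open"] == 16
    assert rep.percent_difference == pytest.approx(25.0)
    assert list(rep.disrupted["interaction"]) == ["contact:42:87:i0"]


def test_increase_is_not_disruption():
    rec = _iface_record(45, 90)
    rows = {rec: [0.1] * 4 + [0.2, 0.25, 0.22, 0.18] + [0.9, 0.92, 0.88, 0.91]}
    rep = interface_disruption(make_table(rows, LBL12), _regions(),
                               ("a3", "a7"), CFG)
    assert rep.disrupted.empty          # one-sided: higher is never disrupted


def test_undefined_percent_difference_flagged():
    rec = _iface_record(45, 90)
    rows = {rec: [0.1] * 4 + [0.1] * 4 + [0.1] * 4}
    rep = interface_disruption(make_table(rows, LBL12), _regions(),
                               ("a3", "a7"), CFG)
    assert rep.undefined_percent and rep.percent_difference == 0.0


def test_small_groups_rejected_when_strict():
    rec = _iface_record(45, 90)
    rows = {rec: [0.9] * 4 + [0.9] * 4 + [0.1]}
    table = make_table(rows, LBL8 + ["ligand:AD"])
    with pytest.raises(ValueError, match="< 2"):
        interface_disruption(table, _regions(), ("a3", "a7"), CFG)
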