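"""Named structural regions of a PTP catalytic domain.

A :class:`RegionMap` names the residue ranges that the analysis reasons
about — the WPD and P loops around the active site, the L-11 loop and the
α3/α6/α7 helices forming the C-terminal allosteric site, and the β8-β10
sheets lining the secondary (β) pocket — plus the identities of the two
catalytic residues whose Cα-Cα distance classifies the WPD loop (the
catalytic acid, D181 in PTP1B / D182 in TCPTP, and the nucleophile,
C215 / C216).

Residue indices are 0-based topology indices internally. YAML files may
declare ``indexing: resSeq`` to use author (PDB) numbering, which is mapped
onto topology indices at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

#: canonical region names, in active-site -> allosteric-site order
REGION_NAMES = ("wpd", "ploop", "l11", "a3", "a6", "a7", "b8", "b9", "b10")

ACTIVE_SITE_REGIONS = ("wpd", "ploop")
ALLOSTERIC_SITE_REGIONS = ("l11", "a3", "a6", "a7")


@dataclass
class RegionMap:
    """Residue ranges (half-open ``[start, stop)``) per named region plus
    catalytic residue identities."""

    regions: dict[str, tuple[int, int]]
    catalytic_acid: int
    nucleophile: int
    indexing: str = "0-based"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.catalytic_acid == self.nucleophile:
            raise ValueError("catalytic_acid and nucleophile must differ")
        for name, (lo, hi) in self.regions.items():
            if hi <= lo or lo < 0:
                raise ValueError(f"region {name!r} has empty/negative range ({lo}, {hi})")

    def residues(self, name: str) -> range:
        lo, hi = self.regions[name]
        return range(lo, hi)

    def region_of(self, residue: int) -> str | None:
        for name, (lo, hi) in self.regions.items():
            if lo <= residue < hi:
                return name
        return None

    def active_site_residues(self) -> set[int]:
        out: set[int] = set()
        for name in ACTIVE_SITE_REGIONS:
            if name in self.regions:
                out |= set(self.residues(name))
        return out

    def allosteric_site_residues(self) -> set[int]:
        out: set[int] = set()
        for name in ALLOSTERIC_SITE_REGIONS:
            if name in self.regions:
                out |= set(self.residues(name))
        return out

    def validate_against(self, topology) -> list[str]:
        """Check every referenced residue resolves in an mdtraj Topology.
        Returns a list of problems (empty = ok)."""
        problems = []
        n = topology.n_residues
        for name, (lo, hi) in self.regions.items():
            if hi > n:
                problems.append(f"region {name!r} range ({lo}, {hi}) exceeds "
                                f"topology ({n} residues)")
        for label, idx in (("catalytic_acid", self.catalytic_acid),
                           ("nucleophile", self.nucleophile)):
            if not 0 <= idx < n:
                problems.append(f"{label} residue {idx} not in topology")
        return problems

    # ------------------------------------------------------------------ IO
    def to_yaml(self, path) -> None:
        data = {
            "indexing": self.indexing,
            "catalytic_acid": int(self.catalytic_acid),
            "nucleophile": int(self.nucleophile),
            "regions": {k: [int(a), int(b)] for k, (a, b) in self.regions.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path, topology=None) -> "RegionMap":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        indexing = data.get("indexing", "0-based")
        regions = {k: (int(v[0]), int(v[1])) for k, v in data["regions"].items()}
        acid = int(data["catalytic_acid"])
        nuc = int(data["nucleophile"])
        if indexing == "resSeq":
            if topology is None:
                raise ValueError("resSeq indexing requires a topology to map "
                                 "author numbering onto residue indices")
            seq2idx = {r.resSeq: r.index for r in topology.residues}
            def _m(s):  # map a resSeq to topology index
                if s not in seq2idx:
                    raise ValueError(f"resSeq {s} not found in topology")
                return seq2idx[s]
            regions = {k: (_m(a), _m(b - 1) + 1) for k, (a, b) in regions.items()}
            acid, nuc = _m(acid), _m(nuc)
            indexing = "0-based"
        return cls(regions=regions, catalytic_acid=acid, nucleophile=nuc,
                   indexing=indexing)
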