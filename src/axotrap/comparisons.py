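"""The twelve-comparison design over the eight sample groups.

Four comparisons within the TRAP fraction (axon vs cortex in each
condition; trained vs control in each compartment), the same four on
the tissue transcriptome, and a direct TRAP-vs-transcriptome
comparison in each of the four compartment x condition cells.

Sign convention (fixed globally and stated in output headers):
axon-vs-cortex reports log2FC of axon over cortex; trained-vs-control
reports trained over control; TRAP-vs-transcriptome reports TRAP over
transcriptome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .dge import COMPARTMENTS, CONDITIONS, CountMatrix, size_factors, test_dge

__all__ = [
    "ComparisonSet",
    "COMPARISON_NAMES",
    "TRAP_COMPARISONS",
    "comparison_groups",
    "run_comparisons",
]

_FRACTION_TAG = {"trap": "trap", "transcriptome": "txm"}


def _design() -> list[dict]:
    specs = []
    for frac in ("trap", "transcriptome"):
        tag = _FRACTION_TAG[frac]
        for cond in CONDITIONS:
            specs.append({
                "name": f"{tag}_axon_vs_cortex_{cond}",
                "kind": "enrichment",
                "a": {"fraction": frac, "compartment": "cortex", "condition": cond},
                "b": {"fraction": frac, "compartment": "axon", "condition": cond},
            })
        for comp in COMPARTMENTS:
            specs.append({
                "name": f"{tag}_trained_vs_control_{comp}",
                "kind": "learning",
                "a": {"fraction": frac, "compartment": comp, "condition": "control"},
                "b": {"fraction": frac, "compartment": comp, "condition": "trained"},
            })
    for comp in COMPARTMENTS:
        for cond in CONDITIONS:
            specs.append({
                "name": f"trap_vs_txm_{comp}_{cond}",
                "kind": "ip_enrichment",
                "a": {"fraction": "transcriptome", "compartment": comp, "condition": cond},
                "b": {"fraction": "trap", "compartment": comp, "condition": cond},
            })
    return specs


_DESIGN = _design()
COMPARISON_NAMES = [s["name"] for s in _DESIGN]
#: The four TRAP comparisons the filter operates on.
TRAP_COMPARISONS = [s["name"] for s in _DESIGN
                    if s["name"].startswith("trap_") and not s["name"].startswith("trap_vs_")]

#: TRAP comparison -> its transcriptome twin.
TWIN_MAP = {name: "txm" + name[len("trap"):] for name in TRAP_COMPARISONS}

#: (compartment, condition) design cell -> its TRAP-vs-transcriptome comparison.
CELL_MAP = {(comp, cond): f"trap_vs_txm_{comp}_{cond}"
            for comp in COMPARTMENTS for cond in CONDITIONS}


def comparison_groups(name: str) -> tuple[dict, dict]:
    """The (A, B) design-cell selectors of a named comparison."""
    for s in _DESIGN:
        if s["name"] == name:
            return s["a"], s["b"]
    raise KeyError(name)


@dataclass
class ComparisonSet:
    """The twelve named DGE tables plus the correspondence maps."""

    tables: dict[str, pd.DataFrame]
    alpha: float = 0.05
    twin_map: dict[str, str] = field(default_factory=lambda: dict(TWIN_MAP))
    cell_map: dict[tuple[str, str], str] = field(default_factory=lambda: dict(CELL_MAP))

    def __post_init__(self) -> None:
        missing = set(COMPARISON_NAMES) - set(self.tables)
        if missing:
            raise ValueError(f"missing comparisons: {sorted(missing)}")
        extra = set(self.tables) - set(COMPARISON_NAMES)
        if extra:
            raise ValueError(f"unknown comparisons: {sorted(extra)}")
        universes = {name: tuple(t.index) for name, t in self.tables.items()}
        ref = universes[COMPARISON_NAMES[0]]
        for name, u in universes.items():
            if u != ref:
                raise ValueError(f"gene universe of {name!r} differs from the others")

    @property
    def gene_ids(self) -> pd.Index:
        return self.tables[COMPARISON_NAMES[0]].index

    def __getitem__(self, name: str) -> pd.DataFrame:
        return self.tables[name]


def run_comparisons(cm: CountMatrix, alpha: float = 0.05) -> ComparisonSet:
    """Run all twelve DGE comparisons on an 8-group count matrix.

    Size factors are estimated once on the full matrix so every
    comparison shares one normalization.  Raises if any design cell is
    missing or has fewer than two replicates, naming the cell.
    """
    groups = cm.groups()
    from .simulate import GROUP_ORDER  # canonical cell ordering
    for cell in GROUP_ORDER:
        if cell not in groups:
            raise ValueError(f"missing design cell: {cell}")
        if len(groups[cell]) < 2:
            raise ValueError(f"design cell {cell} has fewer than 2 replicates")
    sf = size_factors(cm.counts)
    tables = {}
    for spec in _DESIGN:
        a = cm.samples_in(**spec["a"])
        b = cm.samples_in(**spec["b"])
        tables[spec["name"]] = test_dge(cm.counts, a, b, alpha_fdr=alpha,
                                        sf=sf.loc[a + b])
    return ComparisonSet(tables=tables, alpha=alpha)
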