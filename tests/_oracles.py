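"""Independent brute-force evaluators used as oracles in tests.

These deliberately re-state the filtering rules as literal per-gene
loops, independent of the vectorized implementation they check.
"""

import numpy as np

from axotrap.comparisons import CELL_MAP, TRAP_COMPARISONS, TWIN_MAP


def brute_force_filter(cs, alpha=0.05, strict=True):
    """Gene-by-gene evaluation of the three filter rules.

    Returns {comparison: {gene: (survives, audit_code)}}.
    """
    out = {}
    for comp in TRAP_COMPARISONS:
        trap = cs[comp]
        twin = cs[TWIN_MAP[comp]]
        res = {}
        for gene in trap.index:
            row = trap.loc[gene]
            if not row["tested"]:
                res[gene] = (False, "untested")
                continue
            de = row["padj"] < alpha
            if not de:
                res[gene] = (False, "not_de")
                continue
            direction = 1 if row["log2fc"] > 0 else (-1 if row["log2fc"] < 0 else 0)
            trow = twin.loc[gene]
            if not trow["tested"]:
                res[gene] = (False, "untested")
                continue
            tsig = trow["padj"] < alpha
            tsign = np.sign(trow["log2fc"])
            if tsig and tsign == np.sign(row["log2fc"]):
                res[gene] = (False, "transcriptome_mirror")
                continue
            rule3 = strict or "axon_vs_cortex" in comp
            if rule3:
                if "axon_vs_cortex" in comp:
                    cond = comp.split("_")[-1]
                    cell = ("axon" if direction > 0 else "cortex", cond)
                else:
                    area = comp.split("_")[-1]
                    cell = (area, "trained" if direction > 0 else "control")
                ip = cs[CELL_MAP[cell]].loc[gene]
                if not ip["tested"]:
                    res[gene] = (False, "untested")
                    continue
                if not (ip["padj"] < alpha and ip["log2fc"] > 0):
                    res[gene] = (False, "not_trap_enriched")
                    continue
            res[gene] = (True, "pass")
        out[comp] = res
    return out


def brute_force_labels(cs, alpha=0.05, strict=True):
    """Per-gene axonal/shared/cortex_only/none labels from the brute-force
    filter, by direct application of the translatome definition."""
    dec = brute_force_filter(cs, alpha=alpha, strict=strict)
    labels = {}
    for gene in cs.gene_ids:
        def side(comp):
            surv, _ = dec[comp][gene]
            if not surv:
                return 0
            lfc = cs[comp].loc[gene, "log2fc"]
            return 1 if lfc > 0 else -1
        axonal = (
            side("trap_trained_vs_control_axon") != 0
            or side("trap_axon_vs_cortex_control") > 0
            or side("trap_axon_vs_cortex_trained") > 0
        )
        cortical = (
            side("trap_trained_vs_control_cortex") != 0
            or side("trap_axon_vs_cortex_control") < 0
            or side("trap_axon_vs_cortex_trained") < 0
        )
        if axonal and cortical:
            labels[gene] = "shared"
        elif axonal:
            labels[gene] = "axonal_only"
        elif cortical:
            labels[gene] = "cortex_only"
        else:
            labels[gene] = "none"
    return labels
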