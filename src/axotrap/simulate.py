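"""Synthetic data with known ground truth.

Three generators emulate the statistical structure the downstream
analysis assumes, so every stage is testable without any external
download:

* ``generate_counts`` — an 8-group TRAP-seq / tissue-transcriptome
  count matrix (2 fractions x 2 compartments x 2 conditions) with
  negative-binomially distributed counts, planted learning and
  compartment-enrichment effects, an opposite-direction coupling
  between axon and cortex, TRAP enrichment of neuronal genes, and
  TRAP depletion of non-neuronal background genes.
* ``generate_transcript_table`` — per-transcript FPKM across areas and
  conditions with planted contribution scores.
* ``generate_image_pair`` — two-channel punctate images with a planted
  colocalization fraction for Costes/Manders recovery tests.

All three are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dge import COMPARTMENTS, CONDITIONS, FRACTIONS, CountMatrix

__all__ = [
    "SimConfig",
    "ImageSpec",
    "GROUP_ORDER",
    "generate_counts",
    "expected_labels",
    "generate_transcript_table",
    "generate_image_pair",
]

#: Fixed ordering of the 8 design cells (fraction, compartment, condition).
GROUP_ORDER = [
    (f, c, t) for f in FRACTIONS for c in COMPARTMENTS for t in CONDITIONS
]

LABELS = (
    "axon_up",
    "axon_down",
    "axon_enriched",
    "cortex_up",
    "cortex_down",
    "background",
    "null",
)


@dataclass
class SimConfig:
    """Parameters of the synthetic count simulation.

    The negative binomial is parameterized by mean and dispersion
    ``alpha`` (var = mu + alpha * mu**2), matching the DGE model.
    ``frac_*`` are label proportions; whatever remains is null.
    ``effect_lfc`` / ``enrich_lfc`` are planted |log2 fold changes|;
    ``opposite_coupling`` is the probability that an axon-regulated
    gene carries the opposite-direction learning effect in cortex.
    Genes carrying planted translatome effects are TRAP-enriched over
    the tissue transcriptome by ``trap_enrichment_lfc`` (they are
    neuron-expressed by construction), background genes are depleted
    by ``trap_depletion_lfc``, and null genes show no systematic IP
    bias — so the median gene anchors the normalization and planted
    fold changes survive it.
    """

    n_genes: int = 5000
    n_replicates: int = 4
    seed: int = 0
    baseline_logmean_mu: float = 4.0   # natural-log scale; ~55 counts
    baseline_logmean_sd: float = 1.0
    dispersion: float = 0.05
    frac_axon_up: float = 0.05
    frac_axon_down: float = 0.05
    frac_axon_enriched: float = 0.05
    frac_cortex_regulated: float = 0.10
    frac_background: float = 0.25
    effect_lfc: float = 2.0
    enrich_lfc: float = 2.0
    opposite_coupling: float = 0.4
    trap_depletion_lfc: float = 2.0
    trap_enrichment_lfc: float = 1.0
    library_size_factors: dict[str, float] | None = None
    # transcript-table knobs
    n_transcript_genes: int = 200
    max_transcripts: int = 3
    contribution_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        fracs = self.label_fractions()
        for name, f in fracs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if sum(fracs.values()) > 1.0 + 1e-12:
            raise ValueError("label fractions must sum to <= 1")
        if not 0.0 <= self.opposite_coupling <= 1.0:
            raise ValueError("opposite_coupling must lie in [0, 1]")

    def label_fractions(self) -> dict[str, float]:
        return {
            "frac_axon_up": self.frac_axon_up,
            "frac_axon_down": self.frac_axon_down,
            "frac_axon_enriched": self.frac_axon_enriched,
            "frac_cortex_regulated": self.frac_cortex_regulated,
            "frac_background": self.frac_background,
        }


def _draw_nb(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB draws with var = mu + alpha*mu^2 (Poisson when alpha == 0)."""
    if alpha == 0:
        return rng.poisson(mean)
    size_param = 1.0 / alpha
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def _assign_labels(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    n = cfg.n_genes
    counts = {
        "axon_up": int(round(cfg.frac_axon_up * n)),
        "axon_down": int(round(cfg.frac_axon_down * n)),
        "axon_enriched": int(round(cfg.frac_axon_enriched * n)),
        "background": int(round(cfg.frac_background * n)),
    }
    n_cortex = int(round(cfg.frac_cortex_regulated * n))
    counts["cortex_up"] = n_cortex // 2
    counts["cortex_down"] = n_cortex - n_cortex // 2
    total = sum(counts.values())
    if total > n:
        raise ValueError("label fractions exceed the gene universe")
    labels = np.array(
        [lab for lab, k in counts.items() for _ in range(k)] + ["null"] * (n - total),
        dtype=object,
    )
    rng.shuffle(labels)
    return labels


def generate_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate the 8-group design; returns (CountMatrix, ground truth).

    Learning and enrichment effects are planted in the TRAP fraction
    only — the tissue transcriptome stays flat — so the downstream
    transcriptome-mirror exclusion removes none of them.  The ground
    truth DataFrame (indexed by gene_id) records the label, the
    coupling flag, and the expected mean of every design cell.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"gene{i:05d}" for i in range(cfg.n_genes)]
    labels = _assign_labels(rng, cfg)
    baseline = np.exp(rng.normal(cfg.baseline_logmean_mu, cfg.baseline_logmean_sd, cfg.n_genes))
    coupled = (rng.random(cfg.n_genes) < cfg.opposite_coupling) & np.isin(
        labels, ["axon_up", "axon_down"]
    )

    # log2 multiplier per gene per design cell
    lfc = {g: np.zeros(cfg.n_genes) for g in GROUP_ORDER}
    is_bg = labels == "background"
    is_effect = ~is_bg & (labels != "null")
    trap_bias = np.where(is_bg, -cfg.trap_depletion_lfc,
                         np.where(is_effect, cfg.trap_enrichment_lfc, 0.0))
    for frac, comp, cond in GROUP_ORDER:
        if frac != "trap":
            continue
        lfc[(frac, comp, cond)] = trap_bias.astype(float)

    def add(cell, mask, delta):
        lfc[cell] = lfc[cell] + np.where(mask, delta, 0.0)

    add(("trap", "axon", "trained"), labels == "axon_up", cfg.effect_lfc)
    add(("trap", "axon", "trained"), labels == "axon_down", -cfg.effect_lfc)
    # opposite-direction coupling in cortex
    add(("trap", "cortex", "trained"), (labels == "axon_up") & coupled, -cfg.effect_lfc)
    add(("trap", "cortex", "trained"), (labels == "axon_down") & coupled, cfg.effect_lfc)
    add(("trap", "cortex", "trained"), labels == "cortex_up", cfg.effect_lfc)
    add(("trap", "cortex", "trained"), labels == "cortex_down", -cfg.effect_lfc)
    for cond in CONDITIONS:
        add(("trap", "axon", cond), labels == "axon_enriched", cfg.enrich_lfc)

    means = {cell: baseline * 2.0 ** lfc[cell] for cell in GROUP_ORDER}

    sample_ids, rows = [], []
    for frac, comp, cond in GROUP_ORDER:
        for r in range(1, cfg.n_replicates + 1):
            sid = f"{frac}_{comp}_{cond}_r{r}"
            sample_ids.append(sid)
            rows.append({"sample_id": sid, "fraction": frac, "compartment": comp,
                         "condition": cond, "replicate": r})
    sheet = pd.DataFrame(rows).set_index("sample_id")

    if cfg.library_size_factors is None:
        sf = {sid: float(np.exp(rng.normal(0.0, 0.2))) for sid in sample_ids}
    else:
        sf = dict(cfg.library_size_factors)
        missing = set(sample_ids) - set(sf)
        if missing:
            raise ValueError(f"library_size_factors missing samples: {sorted(missing)}")

    mat = np.empty((cfg.n_genes, len(sample_ids)), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        cell = (sheet.loc[sid, "fraction"], sheet.loc[sid, "compartment"], sheet.loc[sid, "condition"])
        mat[:, j] = _draw_nb(rng, means[cell] * sf[sid], cfg.dispersion)
    counts = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)

    truth = pd.DataFrame({"label": labels, "coupled": coupled},
                         index=pd.Index(gene_ids, name="gene_id"))
    for cell in GROUP_ORDER:
        truth["mean_" + "_".join(cell)] = means[cell]
    return CountMatrix(counts, sheet), truth


def expected_labels(truth: pd.DataFrame, rtol: float = 1e-6) -> pd.DataFrame:
    """Ideal classification implied by the planted group means.

    Applies the translatome definition to the noiseless expected means:
    a gene is truly axonal if its planted means make it learning-
    regulated in TRAP axons or axon-side enriched vs cortex in either
    condition, with the enriched-side cell also TRAP-enriched over its
    transcriptome (the enrichment-confirmation rule in expectation).
    Note a cortex-regulated gene whose trained-condition drop creates a
    genuine axon-side enrichment is truly *shared* under this
    definition, exactly as in the analysis itself.

    Returns a DataFrame with boolean columns true_axonal,
    true_cortical and the expected label.
    """
    def m(frac, comp, cond):
        return truth[f"mean_{frac}_{comp}_{cond}"].to_numpy(float)

    def gt(a, b):
        return a > b * (1.0 + rtol)

    def confirmed(comp, cond):
        return gt(m("trap", comp, cond), m("transcriptome", comp, cond))

    out = pd.DataFrame(index=truth.index)
    flags = {}
    for comp in COMPARTMENTS:
        trained, control = m("trap", comp, "trained"), m("trap", comp, "control")
        up, down = gt(trained, control), gt(control, trained)
        flags[comp] = (up & confirmed(comp, "trained")) | (down & confirmed(comp, "control"))
    for cond in CONDITIONS:
        ax, cx = m("trap", "axon", cond), m("trap", "cortex", cond)
        flags["axon"] = flags["axon"] | (gt(ax, cx) & confirmed("axon", cond))
        flags["cortex"] = flags["cortex"] | (gt(cx, ax) & confirmed("cortex", cond))
    out["true_axonal"] = flags["axon"]
    out["true_cortical"] = flags["cortex"]
    out["expected_label"] = np.select(
        [flags["axon"] & flags["cortex"], flags["axon"], flags["cortex"]],
        ["shared", "axonal_only", "cortex_only"],
        default="none",
    )
    return out


# ---------------------------------------------------------------------------
# transcript-level fixture


def generate_transcript_table(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-transcript FPKM table with planted contribution scores.

    Each simulated gene carries 1..max_transcripts transcripts and a
    gene-level learning effect (Delta FPKM) in each area; the effect is
    split across transcripts by Dirichlet weights, with the cortex
    weights perturbed around the axon weights by ``contribution_noise_sd``
    so the two areas' scores are correlated but not identical.  Gene
    FPKM is the sum of its transcripts' FPKM in every group by
    construction.

    Returns ``(table, truth)``: the table has one row per
    (gene_id, transcript_id) with columns fpkm_{area}_{condition}; the
    truth records the planted per-area contribution scores.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 1)
    rows, truth_rows = [], []
    for gi in range(cfg.n_transcript_genes):
        gene = f"tgene{gi:04d}"
        n_t = int(rng.integers(1, cfg.max_transcripts + 1))
        # opposite-direction gene-level effects, axon up / cortex down or vice versa
        sign = 1.0 if rng.random() < 0.5 else -1.0
        delta_gene = {"axon": sign * float(np.exp(rng.normal(1.5, 0.4))),
                      "cortex": -sign * float(np.exp(rng.normal(1.5, 0.4)))}
        w_axon = rng.dirichlet(np.full(n_t, 5.0))
        w_cortex = w_axon + rng.normal(0.0, cfg.contribution_noise_sd, n_t)
        w_cortex = w_cortex - (w_cortex.sum() - 1.0) / n_t  # renormalize to sum 1
        for ti in range(n_t):
            tid = f"{gene}.t{ti + 1}"
            base = {a: float(np.exp(rng.normal(2.5, 0.5))) for a in COMPARTMENTS}
            d = {"axon": w_axon[ti] * delta_gene["axon"],
                 "cortex": w_cortex[ti] * delta_gene["cortex"]}
            row = {"gene_id": gene, "transcript_id": tid}
            for area in COMPARTMENTS:
                control = base[area] + max(0.0, -d[area])  # keep trained FPKM >= 0
                row[f"fpkm_{area}_control"] = control
                row[f"fpkm_{area}_trained"] = control + d[area]
            rows.append(row)
            truth_rows.append({"gene_id": gene, "transcript_id": tid,
                               "c_axon": w_axon[ti], "c_cortex": w_cortex[ti]})
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return table, truth


# ---------------------------------------------------------------------------
# image fixture


@dataclass
class ImageSpec:
    """Two-channel punctate image simulation parameters.

    ``coloc_fraction`` of channel-2 puncta are placed exactly on
    channel-1 punctum centers; the rest are rejection-sampled away from
    every channel-1 punctum.  Puncta are symmetric 2-D Gaussians added
    to Gaussian background clipped at zero.  ``roi_masks`` optionally
    names binary regions (e.g. soma / neuropil) with per-ROI
    ``roi_coloc_fraction`` overrides.
    """

    width: int = 256
    height: int = 256
    n_puncta_ch1: int = 150
    n_puncta_ch2: int = 150
    coloc_fraction: float = 0.5
    punctum_amplitude: float = 100.0
    punctum_sigma: float = 1.5
    background_mean: float = 2.0
    background_sd: float = 0.5
    roi_masks: dict[str, np.ndarray] | None = None
    roi_coloc_fraction: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        if self.roi_masks:
            occupancy = np.zeros((self.height, self.width), dtype=int)
            for name, mask in self.roi_masks.items():
                mask = np.asarray(mask, dtype=bool)
                if mask.shape != (self.height, self.width):
                    raise ValueError(
                        f"ROI mask {name!r} shape {mask.shape} exceeds or mismatches "
                        f"image bounds {(self.height, self.width)}"
                    )
                occupancy += mask
            if (occupancy > 1).any():
                raise ValueError("ROI masks must be disjoint")
        if self.roi_coloc_fraction:
            for name, f in self.roi_coloc_fraction.items():
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"roi coloc fraction for {name!r} must lie in [0, 1]")


def _stamp_gaussians(img: np.ndarray, centers: np.ndarray, amp: float, sigma: float) -> None:
    h, w = img.shape
    half = max(1, int(np.ceil(4 * sigma)))
    win = np.arange(-half, half + 1)
    yy, xx = np.meshgrid(win, win, indexing="ij")
    kernel = amp * np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
    for cy, cx in centers:
        iy, ix = int(round(cy)), int(round(cx))
        y0, y1 = max(0, iy - half), min(h, iy + half + 1)
        x0, x1 = max(0, ix - half), min(w, ix + half + 1)
        ky0, kx0 = y0 - (iy - half), x0 - (ix - half)
        img[y0:y1, x0:x1] += kernel[ky0:ky0 + (y1 - y0), kx0:kx0 + (x1 - x0)]


def generate_image_pair(spec: ImageSpec):
    """Simulate a registered two-channel image pair.

    Returns an :class:`~axotrap.coloc.ImagePair` plus a ground-truth
    dict with punctum centers and per-punctum colocalization flags.
    """
    from .coloc import ImagePair  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    margin = max(2.0, 4 * spec.punctum_sigma)

    def uniform_pos(n):
        return np.column_stack([
            rng.uniform(margin, h - margin, n),
            rng.uniform(margin, w - margin, n),
        ])

    ch1_centers = uniform_pos(spec.n_puncta_ch1)

    def region_of(pos):
        if not spec.roi_masks:
            return None
        iy, ix = int(round(pos[0])), int(round(pos[1]))
        for name, mask in spec.roi_masks.items():
            if np.asarray(mask, dtype=bool)[iy, ix]:
                return name
        return None

    min_sep = 5 * spec.punctum_sigma
    ch2_centers = np.empty((spec.n_puncta_ch2, 2))
    coloc_flags = np.zeros(spec.n_puncta_ch2, dtype=bool)
    for i in range(spec.n_puncta_ch2):
        pos = uniform_pos(1)[0]
        region = region_of(pos)
        f = spec.coloc_fraction
        if region is not None and spec.roi_coloc_fraction:
            f = spec.roi_coloc_fraction.get(region, f)
        if rng.random() < f and len(ch1_centers):
            if region is not None:
                in_region = [k for k in range(len(ch1_centers))
                             if region_of(ch1_centers[k]) == region]
                pool = in_region or list(range(len(ch1_centers)))
            else:
                pool = list(range(len(ch1_centers)))
            pos = ch1_centers[pool[int(rng.integers(len(pool)))]]
            coloc_flags[i] = True
        else:
            for _ in range(200):
                d2 = ((ch1_centers - pos) ** 2).sum(axis=1)
                if d2.size == 0 or d2.min() >= min_sep**2:
                    break
                pos = uniform_pos(1)[0]
        ch2_centers[i] = pos

    ch1 = np.zeros((h, w))
    ch2 = np.zeros((h, w))
    _stamp_gaussians(ch1, ch1_centers, spec.punctum_amplitude, spec.punctum_sigma)
    _stamp_gaussians(ch2, ch2_centers, spec.punctum_amplitude, spec.punctum_sigma)
    ch1 += np.clip(rng.normal(spec.background_mean, spec.background_sd, (h, w)), 0, None)
    ch2 += np.clip(rng.normal(spec.background_mean, spec.background_sd, (h, w)), 0, None)

    masks = {k: np.asarray(v, dtype=bool) for k, v in (spec.roi_masks or {}).items()}
    pair = ImagePair(ch1=ch1, ch2=ch2, roi_masks=masks)
    truth = {"ch1_centers": ch1_centers, "ch2_centers": ch2_centers,
             "ch2_colocalized": coloc_flags}
    return pair, truth
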