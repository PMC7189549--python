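"""Canned desk-scale experiments combining the pipeline stages.

These functions bundle the study designs used for validation: a
rank-structure recovery experiment (does the pipeline's score ordering
recover a planted ordinal severity?) and a gray-matter restriction
experiment (how do scores shift when scoring is restricted to gray
matter?).  Both run on generator heatmaps, whole pipeline, no classifier.
"""

from __future__ import annotations

import numpy as np

from .cohort_stats import spearman_ordinal
from .fov import FOVConfig, compute_fov_scores, select_top_n_nonoverlapping
from .scoring import MorphologyParams, RegionMask, compute_score, percent_change
from .synthetic import SyntheticCohortSpec, generate_cohort, generate_heatmap

DEFAULT_N_VALUES = (1, 3, 5, 7, 9, 11, 13, 15)


def noise_sd_from_gap_fraction(cohort_spec: SyntheticCohortSpec, cls: str, fraction: float) -> float:
    """Noise standard deviation as a fraction of the mean inter-level density gap."""
    dmap = cohort_spec.density_by_level[cls]
    vals = [dmap[lv] for lv in cohort_spec.ordinal_levels]
    gaps = np.diff(vals)
    return float(fraction * gaps.mean())


def cohort_rank_experiment(
    seed: int,
    n_slides: int = 40,
    cls: str = "cored",
    noise_fraction: float = 0.1,
    fov_config: FOVConfig | None = None,
    n_values=DEFAULT_N_VALUES,
    slide_kwargs: dict | None = None,
):
    """One cohort draw: whole-tissue and mean-top-n FOV rank correlations.

    Generates a cohort whose planted densities are monotone in the ordinal
    level with Gaussian noise of ``noise_fraction`` times the mean
    inter-level gap, runs heatmap scoring and field-of-view analysis per
    slide, and returns ``{"wt_rho": float, "rho_by_n": {n: float}}``.

    Default conditions: 8192-px slides (497 x 497 heatmaps, a desk-scale
    stand-in for gigapixel sections), deposits aggregated in several random
    patches (``cluster_sigma_frac`` 0.06), and a scaled-down FOV grid of
    48-px windows at stride 8 so that well over 15 disjoint deposit-bearing
    windows exist per slide.
    """
    if fov_config is None:
        fov_config = FOVConfig(window_size_px=48, window_stride_px=8)
    if slide_kwargs is None:
        slide_kwargs = {
            "width_px": 8192,
            "height_px": 8192,
            "cluster_sigma_frac": 0.06,
        }
    base = SyntheticCohortSpec()
    noise_sd = noise_sd_from_gap_fraction(base, cls, noise_fraction)
    cohort = SyntheticCohortSpec(
        n_slides=n_slides,
        noise_sd=noise_sd,
        seed=seed,
        slide_kwargs=slide_kwargs or {},
    )
    slide_specs, records = generate_cohort(cohort)
    params = MorphologyParams()
    levels = records[f"level_index_{cls}"].to_numpy()

    n_max = max(n_values)
    wt_scores = []
    selected_scores = []  # per slide: greedy non-overlapping top-n_max scores
    for spec in slide_specs:
        heatmap, gt = generate_heatmap(spec, cls)
        region = RegionMask(mask=gt.tissue_mask)
        wt_scores.append(compute_score(heatmap, cls, params, region, "s").cnn_score)
        windows = compute_fov_scores(heatmap, cls, params, gt.tissue_mask, fov_config)
        # greedy selection for n is a prefix of the selection for n_max
        selected = select_top_n_nonoverlapping(windows, n_max)
        selected_scores.append([fw.fov_score for fw in selected])

    wt_rho = spearman_ordinal(np.asarray(wt_scores), levels)
    rho_by_n = {}
    for n in n_values:
        top = np.array(
            [np.mean(s[:n]) if s else 0.0 for s in selected_scores]
        )
        rho_by_n[n] = spearman_ordinal(top, levels)
    return {"wt_rho": wt_rho, "rho_by_n": rho_by_n}


def gray_matter_experiment(
    seed: int,
    n_slides: int = 12,
    white_matter_leak: float = 0.15,
    classes=("cored", "diffuse", "caa"),
    slide_kwargs: dict | None = None,
):
    """Average percent change of gray-matter vs whole-tissue scores per class.

    Slides plant ``white_matter_leak`` of deposits outside the gray matter;
    the gray-matter-restricted score divides the remaining deposits by the
    smaller gray-matter area.  Returns ``{class: mean percent change}``
    over slides with a non-zero whole-tissue score.
    """
    kwargs = dict(slide_kwargs or {})
    kwargs["white_matter_leak"] = white_matter_leak
    cohort = SyntheticCohortSpec(n_slides=n_slides, seed=seed, slide_kwargs=kwargs)
    slide_specs, _ = generate_cohort(cohort)
    params = MorphologyParams()
    out = {}
    for cls in classes:
        changes = []
        for spec in slide_specs:
            heatmap, gt = generate_heatmap(spec, cls)
            wt = compute_score(heatmap, cls, params, RegionMask(mask=gt.tissue_mask), "s")
            gm = compute_score(
                heatmap, cls, params,
                RegionMask(mask=gt.gm_mask, label="gray_matter"), "s",
            )
            pc = percent_change(gm, wt)
            if np.isfinite(pc):
                changes.append(pc)
        out[cls] = float(np.mean(changes)) if changes else float("nan")
    return out
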