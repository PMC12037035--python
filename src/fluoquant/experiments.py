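"""End-to-end simulated experiments built from the module pipelines.

These drive the full simulate → detect → score → compare chain at reduced
scale, e.g. the two-condition recruitment comparison (a "WT vs KO"-style
design with per-image recruited fractions compared by rank test).
"""

from __future__ import annotations

import numpy as np

from . import synapse as syn
from . import synthetic

__all__ = ["score_simulated_image", "recruitment_experiment", "recruitment_power"]


def _draw_ratio(rng: np.random.Generator, p_recruited: float) -> float:
    """Enrichment ratio with P(ratio >= 1.5) = p_recruited, margin >= 0.3."""
    if rng.uniform() < p_recruited:
        return float(rng.uniform(1.8, 2.6))
    return float(rng.uniform(0.7, 1.2))


# compact conjugate geometry so a full two-condition power experiment
# stays within a desktop time budget
SMALL_SCENE = {
    "b_radius_um": 2.0,
    "t_radius_um": 1.8,
    "pixel_size_um": 0.15,
    "contact_halfwidth_um": 0.9,
}
# the synthetic contact zone covers ~13% of the CD3 foreground, so the
# top-percentile cut is matched to the scene geometry
SMALL_SCENE_TOP_PERCENT = 15.0


def score_simulated_image(
    n_synapses: int,
    p_recruited: float,
    rng: np.random.Generator,
    noise_sd: float = 2.0,
) -> list[syn.SynapseRecord]:
    """Simulate one image's synapses through the full pipeline.

    Each synapse is one small conjugate scene run through detection and
    recruitment scoring; undetected contacts are scored on the true mask
    so no synapse silently disappears.
    """
    records = []
    for k in range(n_synapses):
        ratio = _draw_ratio(rng, p_recruited)
        seed = int(rng.integers(0, 2**31 - 1))
        scene, truth = synthetic.simulate_synapse_scene(
            n_pairs=1, enrichment_ratio=ratio, noise_sd=noise_sd, seed=seed,
            **SMALL_SCENE,
        )
        contacts = syn.detect_synapses(
            scene, cd3_top_percent=SMALL_SCENE_TOP_PERCENT
        )
        if contacts:
            contact = max(contacts, key=lambda c: int((c.labels > 0).sum()))
        else:
            contact = truth.arrays["contact_masks"][0]
        records.append(
            syn.score_recruitment(
                scene, contact, synapse_id=k + 1, seed=seed
            )
        )
    return records


def recruitment_experiment(
    n_images: int = 30,
    n_synapses_per_image: int = 10,
    p_recruited_a: float = 0.6,
    p_recruited_b: float = 0.25,
    noise_sd: float = 2.0,
    seed: int = 0,
):
    """One two-condition replicate: per-image summaries plus rank-test p."""
    rng = np.random.default_rng(seed)
    group_a = [
        score_simulated_image(n_synapses_per_image, p_recruited_a, rng, noise_sd)
        for _ in range(n_images)
    ]
    group_b = [
        score_simulated_image(n_synapses_per_image, p_recruited_b, rng, noise_sd)
        for _ in range(n_images)
    ]
    return syn.compare_groups(group_a, group_b)


def recruitment_power(
    n_replicates: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    **kwargs,
) -> float:
    """Fraction of seeded replicates whose rank-test p falls below alpha."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        table = recruitment_experiment(seed=rep_seed, **kwargs)
        p = table["rank_test_p"].iloc[0]
        if np.isfinite(p) and p < alpha:
            hits += 1
    return hits / n_replicates
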