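"""End-to-end conveniences tying the pipeline stages together.

These wrap the canonical study conditions — a ~500-variant library with 20
synonymous control positions, two replicates, quantile-gated bins and 100x
read depth per variant per bin — so simulation studies (null calibration,
parameter recovery, clinical-band classification) can be re-run from a single
seed.
"""

from __future__ import annotations

import numpy as np

from . import clinical as clin
from . import design as design_mod
from . import simulate as sim_mod
from .counts import COUNT_COLUMNS, VariantCountTable
from .scoring import SortSeqEnrichment, SortSeqEnrichmentResults

__all__ = [
    "demo_library",
    "simulate_and_score",
    "null_calibration",
    "clinical_recovery_benchmark",
]

N_SYNONYMOUS_POSITIONS = 20


def demo_library(
    n_positions: int = 27, n_syn_positions: int = N_SYNONYMOUS_POSITIONS, seed: int = 7
) -> design_mod.LibraryDesign:
    """A small saturation library (~500 missense variants + synonymous controls).

    The sequence is random but avoids single-codon residues (M, W) outside
    position 1 so every control position can host a synonymous codon.
    """
    rng = np.random.default_rng(seed)
    seq = "M" + "".join(
        rng.choice(list("ACDEFGHIKLNPQRSTVY"), n_positions + 2)
    )
    lib = design_mod.enumerate_missense(seq, (2, n_positions + 1), rng_seed=seed)
    syn_positions = list(range(2, 2 + n_syn_positions))
    return design_mod.add_synonymous_controls(lib, syn_positions, rng_seed=seed + 1)


def simulate_and_score(
    library: design_mod.LibraryDesign,
    model: sim_mod.PhenotypeModel,
    sort_spec: sim_mod.SortSpec,
    seed: int,
    depth_per_variant: int = 100,
    unexpected_rate: float = 0.005,
) -> tuple[sim_mod.SimulatedExperiment, SortSeqEnrichmentResults]:
    """Simulate one experiment and fit the enrichment model."""
    exp = sim_mod.simulate_experiment(
        library,
        model,
        sort_spec,
        depth_per_bin=depth_per_variant * len(library.variants),
        unexpected_rate=unexpected_rate,
        seed=seed,
    )
    results = SortSeqEnrichment.from_simulation(exp).fit()
    return exp, results


def null_calibration(seed: int, library=None) -> dict:
    """Score an experiment where every variant shares the synonymous latent
    distribution; under the null the missense median should sit at 0 within
    its pooled uncertainty.

    The pooled SE combines per-variant measurement error with the sampling
    uncertainty of the synonymous wildtype reference:
    sqrt(median(se_missense)^2 + var(synonymous scores)/n_synonymous).
    """
    if library is None:
        library = demo_library()
    model = sim_mod.surface_model()
    null_model = sim_mod.PhenotypeModel(
        axis="surface",
        mixture=[(1.0, model.synonymous_mean, model.synonymous_sd)],
        synonymous_mean=model.synonymous_mean,
        synonymous_sd=model.synonymous_sd,
        cell_noise_sd=model.cell_noise_sd,
    )
    _, res = simulate_and_score(
        library, null_model, sim_mod.surface_sort_spec(), seed
    )
    mis, syn = res.missense, res.synonymous
    pooled_se = float(
        np.sqrt(
            np.median(mis["se"]) ** 2 + syn["score"].var(ddof=1) / len(syn)
        )
    )
    return {
        "missense_median": float(mis["score"].median()),
        "pooled_se": pooled_se,
        "n_missense": len(mis),
        "results": res,
    }


def clinical_recovery_benchmark(
    seed: int,
    library=None,
    n_benign: int = 250,
    shift: float = -3.0,
) -> dict:
    """Synthetic clinical benchmark for band-based variant classification.

    ``n_benign`` missense variants take latent effects from the synonymous
    distribution (expert-reviewed benign); the remaining missense variants are
    shifted by ``shift`` log units (pathogenic, reported as VUS).  The neutral
    band is the benign-set 10th–90th percentile; loss sensitivity is measured
    on the pathogenic set and the false-loss rate on the benign set itself —
    the same in-sample sense in which the percentile band is defined.
    """
    if library is None:
        library = demo_library()
    model = sim_mod.surface_model()
    spec = sim_mod.surface_sort_spec()
    ss = np.random.SeedSequence(seed)
    s_latents, s_labels, s_sort, s_reads = ss.spawn(4)
    latents = sim_mod.simulate_phenotypes(library, model, s_latents)
    rng = np.random.default_rng(s_labels)
    mis_mask = (latents["kind"] == "missense").to_numpy()
    latents.loc[mis_mask, "latent"] = rng.normal(
        model.synonymous_mean, model.synonymous_sd, mis_mask.sum()
    )
    mis_idx = latents.index[mis_mask].to_numpy()
    benign_idx = rng.choice(mis_idx, size=n_benign, replace=False)
    path_idx = np.setdiff1d(mis_idx, benign_idx)
    latents.loc[path_idx, "latent"] = rng.normal(
        model.synonymous_mean + shift, model.synonymous_sd, len(path_idx)
    )
    truth = sim_mod.simulate_sort(latents, spec, model.cell_noise_sd, s_sort)
    counts_df, unexpected = sim_mod.simulate_reads(
        truth, spec, 100 * len(library.variants), 0.005, s_reads
    )
    table = VariantCountTable(counts_df[COUNT_COLUMNS], unexpected)
    res = SortSeqEnrichment(table, library, spec).fit()

    meta = latents.loc[mis_mask, ["variant", "position", "wt_aa", "mut_aa"]].copy()
    meta["truth"] = np.where(latents.index[mis_mask].isin(benign_idx), "benign", "pathogenic")
    ctab = meta.assign(label=np.where(meta["truth"] == "benign", "benign", "VUS"))
    band = clin.neutral_band(res.scores, ctab, "surface")
    preds = clin.classify_variants({"surface": res.scores}, {"surface": band}, ctab)
    preds = preds.merge(
        meta[["position", "mut_aa", "truth"]].drop_duplicates(), on=["position", "mut_aa"]
    )
    loss = preds["predicted"].str.contains("loss_of_surface")
    return {
        "band": band,
        "predictions": preds,
        "sensitivity": float(loss[preds["truth"] == "pathogenic"].mean()),
        "false_loss_rate": float(loss[preds["truth"] == "benign"].mean()),
        "results": res,
    }
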