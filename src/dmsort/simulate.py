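"""Synthetic sort-seq experiment generator.

Emulates the observable structure of a FACS-based deep-mutational-scan:

1. every programmed variant carries a latent phenotypic effect drawn from a
   Gaussian mixture (bimodal for surface expression — a wildtype-like mode and
   a strongly trafficking-deficient mode; unimodal for channel function);
2. cells carrying library variants acquire a noisy fluorescence value
   (latent effect + per-cell Gaussian noise) and are gated into ordered sort
   bins at quantiles of the pooled fluorescence distribution, replicate by
   replicate;
3. each bin is sequenced to a fixed read depth with multinomial sampling over
   the variant cell fractions, and a small fraction of reads is corrupted into
   "unexpected" (non-programmed) codon calls.

Latent effects live directly on the log-enrichment scale, so scoring-module
recovery can be checked against ground truth without modelling fluorophore
physics.  The ground truth (latents and true per-bin cell counts) is retained
on the returned experiment object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import LibraryDesign

__all__ = [
    "PhenotypeModel",
    "SortSpec",
    "GroundTruth",
    "SimulatedExperiment",
    "surface_model",
    "function_model",
    "surface_sort_spec",
    "function_sort_spec",
    "simulate_phenotypes",
    "simulate_sort",
    "simulate_reads",
    "simulate_experiment",
]


class SimulationConfigError(ValueError):
    pass


@dataclass
class PhenotypeModel:
    """Latent-effect distribution for one phenotype axis.

    ``mixture`` is a list of (weight, mean, sd) Gaussian components for
    missense variants; synonymous controls are drawn from their own Gaussian.
    ``cell_noise_sd`` is the per-cell fluorescence noise around the latent.
    """

    axis: str
    mixture: list[tuple[float, float, float]]
    synonymous_mean: float = 0.0
    synonymous_sd: float = 0.2
    cell_noise_sd: float = 0.5

    def __post_init__(self):
        weights = np.array([w for w, _, _ in self.mixture], float)
        if not np.isclose(weights.sum(), 1.0):
            raise SimulationConfigError("mixture weights must sum to 1")
        if any(sd <= 0 for _, _, sd in self.mixture) or self.synonymous_sd <= 0:
            raise SimulationConfigError("component sds must be positive")


@dataclass
class SortSpec:
    """Ordered bin structure of one sorting experiment."""

    axis: str
    bin_labels: list[str]
    gate_quantiles: tuple[float, ...]
    n_cells_per_replicate: int = 100_000
    n_replicates: int = 2

    def __post_init__(self):
        q = np.asarray(self.gate_quantiles, float)
        if len(q) != len(self.bin_labels) - 1:
            raise SimulationConfigError("need one fewer gate than bins")
        if len(q) and (np.diff(q) <= 0).any() or ((q <= 0) | (q >= 1)).any():
            raise SimulationConfigError("gate quantiles must increase in (0,1)")


def surface_model() -> PhenotypeModel:
    """Bimodal surface-expression phenotype: a wildtype-like mode at 0 and a
    trafficking-deficient mode around -4 log units (~40% of variants)."""
    return PhenotypeModel(
        axis="surface",
        mixture=[(0.6, 0.0, 0.4), (0.4, -4.0, 1.0)],
        synonymous_mean=-0.1,
        synonymous_sd=0.4,
        cell_noise_sd=0.5,
    )


def function_model() -> PhenotypeModel:
    """Unimodal channel-function phenotype centred near wildtype."""
    return PhenotypeModel(
        axis="function",
        mixture=[(1.0, 0.04, 0.6)],
        synonymous_mean=0.07,
        synonymous_sd=0.24,
        cell_noise_sd=0.5,
    )


def surface_sort_spec(n_cells_per_replicate=100_000, n_replicates=2) -> SortSpec:
    """Four surface-label bins (none/low/up/high), gated at pooled quartiles."""
    return SortSpec(
        "surface",
        ["negative", "low", "up", "high"],
        (0.25, 0.50, 0.75),
        n_cells_per_replicate,
        n_replicates,
    )


def function_sort_spec(n_cells_per_replicate=100_000, n_replicates=2) -> SortSpec:
    """Three membrane-potential bins (negative/low/up), gated at pooled terciles."""
    return SortSpec(
        "function",
        ["negative", "low", "up"],
        (1 / 3, 2 / 3),
        n_cells_per_replicate,
        n_replicates,
    )


@dataclass
class GroundTruth:
    """Simulator-side truth: latent effects and true per-bin cell counts."""

    latents: pd.DataFrame  # variant, position, mut_aa, mut_codon, kind, latent
    cell_counts: pd.DataFrame  # replicate, bin, variant, cells


@dataclass
class SimulatedExperiment:
    axis: str
    sort_spec: SortSpec
    truth: GroundTruth
    counts: pd.DataFrame  # replicate, bin, variant columns..., count
    unexpected: pd.DataFrame  # replicate, bin, unexpected_count
    design: LibraryDesign | None = None


def _variant_frame(design: LibraryDesign) -> pd.DataFrame:
    df = design.to_frame()
    df["variant"] = [v.variant_id for v in design.variants]
    return df


def simulate_phenotypes(
    design: LibraryDesign, model: PhenotypeModel, seed=None
) -> pd.DataFrame:
    """Draw one latent effect per programmed variant.

    Missense variants come from the mixture; synonymous controls from the
    synonymous Gaussian.  Deterministic given ``seed``.
    """
    if not design.variants:
        raise SimulationConfigError("design has no variants")
    rng = np.random.default_rng(seed)
    df = _variant_frame(design)
    n = len(df)
    weights = np.array([w for w, _, _ in model.mixture])
    means = np.array([m for _, m, _ in model.mixture])
    sds = np.array([s for _, _, s in model.mixture])
    comp = rng.choice(len(weights), size=n, p=weights)
    latent = rng.normal(means[comp], sds[comp])
    syn = (df["kind"] == "synonymous").to_numpy()
    latent[syn] = rng.normal(model.synonymous_mean, model.synonymous_sd, syn.sum())
    df["latent"] = latent
    return df


def simulate_sort(
    latents: pd.DataFrame,
    sort_spec: SortSpec,
    cell_noise_sd: float = 0.5,
    seed=None,
    dispersion: float | None = None,
) -> GroundTruth:
    """Assign cells to variants, add per-cell noise, gate into ordered bins.

    Cells are assigned uniformly over the library unless ``dispersion`` is
    given, in which case per-variant representation is Dirichlet-distributed
    (larger dispersion → more even).  Gates are placed at ``gate_quantiles``
    of the pooled per-replicate fluorescence distribution, mirroring sorter
    practice of gating on the observed population.
    """
    if sort_spec.n_cells_per_replicate <= 0:
        raise SimulationConfigError("n_cells_per_replicate must be positive")
    rng = np.random.default_rng(seed)
    n_var = len(latents)
    lat = latents["latent"].to_numpy()
    k = len(sort_spec.bin_labels)
    records = []
    for rep in range(1, sort_spec.n_replicates + 1):
        if dispersion is None:
            p = np.full(n_var, 1.0 / n_var)
        else:
            p = rng.dirichlet(np.full(n_var, dispersion))
        assign = rng.choice(n_var, size=sort_spec.n_cells_per_replicate, p=p)
        fluor = lat[assign] + rng.normal(
            0.0, cell_noise_sd, sort_spec.n_cells_per_replicate
        )
        if k == 1:
            bins = np.zeros(len(fluor), dtype=int)
        else:
            gates = np.quantile(fluor, sort_spec.gate_quantiles)
            if (np.diff(gates) <= 0).any():
                raise SimulationConfigError("degenerate gates (equal cut values)")
            bins = np.digitize(fluor, gates)
        flat = np.bincount(assign * k + bins, minlength=n_var * k).reshape(n_var, k)
        for b, label in enumerate(sort_spec.bin_labels):
            records.append(
                pd.DataFrame(
                    {
                        "replicate": rep,
                        "bin": label,
                        "variant": latents["variant"],
                        "cells": flat[:, b],
                    }
                )
            )
    return GroundTruth(latents=latents, cell_counts=pd.concat(records, ignore_index=True))


def simulate_reads(
    truth: GroundTruth,
    sort_spec: SortSpec,
    depth_per_bin: int,
    unexpected_rate: float = 0.0,
    seed=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sequence each sorted bin: multinomial reads over variant cell fractions.

    Every read is independently corrupted into an "unexpected" (non-programmed
    codon) call with probability ``unexpected_rate``; expected reads plus the
    unexpected tally always total ``depth_per_bin``.
    """
    if depth_per_bin <= 0:
        raise SimulationConfigError("depth_per_bin must be positive")
    if not 0 <= unexpected_rate < 1:
        raise SimulationConfigError("unexpected_rate must be in [0,1)")
    rng = np.random.default_rng(seed)
    counts, unexpected = [], []
    meta = truth.latents.set_index("variant")
    for (rep, label), grp in truth.cell_counts.groupby(
        ["replicate", "bin"], sort=False
    ):
        cells = grp["cells"].to_numpy(float)
        total = cells.sum()
        if total == 0:  # nothing sorted into this bin: nothing to sequence
            reads = np.zeros(len(grp), dtype=int)
            n_unexp = 0
        else:
            n_unexp = rng.binomial(depth_per_bin, unexpected_rate)
            reads = rng.multinomial(depth_per_bin - n_unexp, cells / total)
        df = grp[["variant"]].copy()
        df.insert(0, "replicate", rep)
        df.insert(1, "bin", label)
        df["count"] = reads
        counts.append(df)
        unexpected.append(
            {"replicate": rep, "bin": label, "unexpected_count": n_unexp}
        )
    count_df = pd.concat(counts, ignore_index=True)
    for col in ("position", "wt_aa", "mut_aa", "mut_codon", "kind"):
        count_df[col] = meta.loc[count_df["variant"], col].to_numpy()
    count_df["axis"] = sort_spec.axis
    return count_df, pd.DataFrame(unexpected).assign(axis=sort_spec.axis)


def simulate_experiment(
    design: LibraryDesign,
    model: PhenotypeModel,
    sort_spec: SortSpec,
    depth_per_bin: int | None = None,
    unexpected_rate: float = 0.005,
    seed=None,
    dispersion: float | None = None,
) -> SimulatedExperiment:
    """Run the full generator: latents → sorted cells → sequenced counts.

    ``depth_per_bin`` defaults to 100 reads per library variant per bin.
    The three stages consume independent streams spawned from ``seed`` so the
    experiment is reproducible end to end.
    """
    if depth_per_bin is None:
        depth_per_bin = 100 * len(design.variants)
    ss = np.random.SeedSequence(seed)
    s_phen, s_sort, s_reads = ss.spawn(3)
    latents = simulate_phenotypes(design, model, s_phen)
    truth = simulate_sort(
        latents, sort_spec, model.cell_noise_sd, s_sort, dispersion=dispersion
    )
    counts, unexpected = simulate_reads(
        truth, sort_spec, depth_per_bin, unexpected_rate, s_reads
    )
    return SimulatedExperiment(
        axis=sort_spec.axis,
        sort_spec=sort_spec,
        truth=truth,
        counts=counts,
        unexpected=unexpected,
        design=design,
    )
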