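"""Synthetic datasets with planted ground truth.

Two generators:

* :func:`simulate_probe_dataset` emulates probe-level log2 intensities of
  tandem 3'UTRs: common-region probes see total transcript abundance,
  extended-region probes additionally see the log2 long-isoform fraction.
  Paired normals are generated at the per-tandem baseline fraction so their
  true short-3'UTR index is exactly zero.
* :func:`simulate_screen_counts` emulates a pooled shRNA proliferation
  screen with multinomial sequencing counts and planted hairpin depletion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .normalize import IntensityMatrix, NORMAL, TUMOR

PROBE_LEN = 25
PROBE_SPACING = 60
_F_CLIP_TOL = 1e-6


def default_subtype_effects(
    n_tandems: int,
    n_subtypes: int,
    effect: float = -1.0,
    signature_fraction: float = 0.25,
) -> np.ndarray:
    """Disjoint per-subtype signature blocks of log2 isoform-fraction shifts.

    The first ``floor(signature_fraction * n_tandems)`` tandems are split
    evenly across subtypes; each block carries ``effect`` (negative =
    3'UTR shortening) in its subtype only.  All other entries are 0.
    """
    eff = np.zeros((n_tandems, n_subtypes))
    per = int(signature_fraction * n_tandems) // n_subtypes
    for k in range(n_subtypes):
        eff[k * per : (k + 1) * per, k] = effect
    return eff


@dataclass
class SimulationConfig:
    """Study conditions for the probe-level generator.

    Defaults mirror a paired tumor/normal microarray cohort: four tumor
    subtypes of 36/36/67/26 samples with 33 normals, six probes per
    common/extended segment, baseline long-isoform fraction 0.8, planted
    subtype-specific shortening of 1 log2 unit on disjoint signature
    tandems, and log2-scale Gaussian noise.
    """

    n_tandems: int = 200
    probes_per_segment: tuple[int, int] = (6, 6)
    n_normals: int = 33
    subtype_sizes: tuple[int, ...] = (36, 36, 67, 26)
    baseline_long_fraction: float | np.ndarray = 0.8
    subtype_effects: np.ndarray | None = None
    abundance_sd: float = 0.5
    probe_affinity_sd: float = 0.5
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tandems < 1 or self.n_normals < 1:
            raise ValueError("n_tandems and n_normals must be >= 1")
        nc, ne = self.probes_per_segment
        if nc < 4 or ne < 4:
            raise ValueError(
                "probes_per_segment must each be >= 4 (tandems with fewer "
                "probes per segment are excluded from analysis)"
            )
        if any(s < 1 for s in self.subtype_sizes):
            raise ValueError("subtype sizes must be >= 1")
        f0 = np.broadcast_to(
            np.asarray(self.baseline_long_fraction, dtype=float), (self.n_tandems,)
        )
        if np.any((f0 <= 0) | (f0 > 1)):
            raise ValueError("baseline_long_fraction must lie in (0, 1]")
        if self.noise_sd < 0 or self.abundance_sd < 0 or self.probe_affinity_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.subtype_effects is not None:
            eff = np.asarray(self.subtype_effects, dtype=float)
            if eff.shape != (self.n_tandems, len(self.subtype_sizes)):
                raise ValueError("subtype_effects must be (n_tandems, n_subtypes)")
            f = f0[:, None] * 2.0 ** eff
            if np.any(f > 1.0 + _F_CLIP_TOL):
                raise ValueError(
                    "subtype_effects imply long-isoform fraction > 1"
                )

    @property
    def f0(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.baseline_long_fraction, dtype=float), (self.n_tandems,)
        ).copy()

    @property
    def effects(self) -> np.ndarray:
        if self.subtype_effects is None:
            return default_subtype_effects(self.n_tandems, len(self.subtype_sizes))
        return np.asarray(self.subtype_effects, dtype=float)


@dataclass
class GroundTruth:
    """Planted truth for a simulated probe dataset.

    ``true_sui`` is log2(f0_t / f_ts); it is 0 for every normal sample by
    construction.  ``true_change_index`` is the 0-based ordinal of the last
    common-segment probe (the boundary after it is the planted change).
    """

    long_fraction: pd.DataFrame  # tandems x samples
    true_change_index: pd.Series  # per tandem
    true_subtype: pd.Series  # per tumor sample
    true_sui: pd.DataFrame  # tandems x samples


def simulate_probe_dataset(
    config: SimulationConfig,
) -> tuple[IntensityMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (intensity matrix, probe map, annotation, ground truth).

    Model: ``y_ps = beta_p + a_ts + [p in extended] * log2(f_ts) + eps`` with
    ``eps ~ N(0, noise_sd^2)``, probe affinities ``beta_p``, per-sample
    abundances ``a_ts``.  Normals use ``f = f0``; tumors scale ``f0`` by
    ``2^effect`` of their subtype, clipped to (0, 1].

    The probe map is BED6, 0-based half-open; minus-strand tandems have
    genomic order reversed relative to transcript order.
    """
    rng = np.random.default_rng(config.seed)
    nc, ne = config.probes_per_segment
    n_probes = nc + ne
    n_sub = len(config.subtype_sizes)
    n_tum = int(sum(config.subtype_sizes))
    f0 = config.f0
    effects = config.effects

    sample_ids = [f"N{i + 1:03d}" for i in range(config.n_normals)]
    groups = [NORMAL] * config.n_normals
    subtype_of: dict[str, str] = {}
    for k, size in enumerate(config.subtype_sizes):
        for i in range(size):
            sid = f"T{len(subtype_of) + 1:03d}"
            sample_ids.append(sid)
            groups.append(TUMOR)
            subtype_of[sid] = f"S{k + 1}"
    n_samples = config.n_normals + n_tum

    # long-isoform fraction per tandem x sample
    f = np.empty((config.n_tandems, n_samples))
    f[:, : config.n_normals] = f0[:, None]
    col = config.n_normals
    for k, size in enumerate(config.subtype_sizes):
        fk = np.minimum(f0 * 2.0 ** effects[:, k], 1.0)
        f[:, col : col + size] = fk[:, None]
        col += size

    probe_rows = []
    ann_rows = []
    blocks = []
    for t in range(config.n_tandems):
        gene = f"G{t + 1:04d}"
        strand = "+" if t % 2 == 0 else "-"
        chrom = f"chr{(t % 22) + 1}"
        g_lo = 10_000 + t * 50_000
        length = n_probes * PROBE_SPACING
        g_hi = g_lo + length

        beta = rng.normal(0.0, config.probe_affinity_sd, n_probes)
        a = rng.normal(0.0, config.abundance_sd, n_samples)
        eps = rng.normal(0.0, config.noise_sd, (n_probes, n_samples))
        y = beta[:, None] + a[None, :] + eps
        y[nc:, :] += np.log2(f[t])[None, :]
        blocks.append(y)

        for i in range(n_probes):  # transcript order
            if strand == "+":
                start = g_lo + i * PROBE_SPACING + 10
            else:
                start = g_hi - i * PROBE_SPACING - 10 - PROBE_LEN
            probe_rows.append(
                (chrom, start, start + PROBE_LEN, f"{gene}_p{i + 1:02d}", 0, strand)
            )
        if strand == "+":
            utr_start, proximal, distal = g_lo, g_lo + nc * PROBE_SPACING, g_hi
        else:
            utr_start, proximal, distal = g_hi, g_hi - nc * PROBE_SPACING, g_lo
        ann_rows.append((gene, f"{gene}.1", chrom, strand, utr_start, proximal))
        ann_rows.append((gene, f"{gene}.2", chrom, strand, utr_start, distal))

    probe_map = pd.DataFrame(
        probe_rows, columns=["chrom", "start", "end", "probe_id", "score", "strand"]
    )
    annotation = pd.DataFrame(
        ann_rows,
        columns=["gene_id", "transcript_id", "chrom", "strand", "utr_start", "utr_end"],
    )
    values = pd.DataFrame(
        np.vstack(blocks), index=probe_map["probe_id"].to_numpy(), columns=sample_ids
    )
    matrix = IntensityMatrix(
        values,
        pd.Series(groups, index=sample_ids),
        pd.Series(subtype_of),
    )
    tandem_ids = [f"G{t + 1:04d}" for t in range(config.n_tandems)]
    truth = GroundTruth(
        long_fraction=pd.DataFrame(f, index=tandem_ids, columns=sample_ids),
        true_change_index=pd.Series(nc - 1, index=tandem_ids),
        true_subtype=pd.Series(subtype_of),
        true_sui=pd.DataFrame(
            np.log2(f0[:, None] / f), index=tandem_ids, columns=sample_ids
        ),
    )
    return matrix, probe_map, annotation, truth


def write_probe_dataset(
    outdir,
    matrix: IntensityMatrix,
    probe_map: pd.DataFrame,
    annotation: pd.DataFrame,
) -> None:
    """Write the TSV/BED artifacts of a simulated probe dataset."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.write(outdir / "intensity.tsv", outdir / "samples.tsv")
    probe_map.to_csv(outdir / "probes.bed", sep="\t", header=False, index=False)
    annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)


def simulate_screen_counts(
    n_genes: int = 23,
    hairpins_per_gene: int = 4,
    n_controls: int = 3,
    depleted_genes: set[str] | None = None,
    depletion_rate: float = 1.0,
    timepoints: tuple[int, ...] = (0, 7, 14, 21),
    n_replicates: int = 2,
    library_size: int = 5_000_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Pooled shRNA screen counts with planted depletion.

    Hairpins of depleted genes lose abundance at ``depletion_rate`` log2
    units per week; every other hairpin (including non-targeting controls)
    is neutral.  At day ``d`` counts are multinomial(library_size, weights
    proportional to ``w_h * 2^(phi_h * d / 7)``), drawn independently per
    replicate so column sums equal the library size exactly.

    Returns (count table, hairpin->gene map, truth dict).
    """
    if 0 not in timepoints:
        raise ValueError("timepoints must include day 0")
    genes = [f"GENE{i + 1:02d}" for i in range(n_genes)]
    depleted = set(depleted_genes or set())
    unknown = depleted - set(genes)
    if unknown:
        raise ValueError(f"depleted_genes not in gene set: {sorted(unknown)}")

    hairpins, gene_of, is_control = [], [], []
    for g in genes:
        for h in range(hairpins_per_gene):
            hairpins.append(f"sh{g}_{h + 1}")
            gene_of.append(g)
            is_control.append(False)
    for c in range(n_controls):
        hairpins.append(f"shCTRL_{c + 1}")
        gene_of.append("CONTROL")
        is_control.append(True)
    n_hp = len(hairpins)
    if library_size < n_hp:
        raise ValueError("library_size smaller than number of hairpins")

    rng = np.random.default_rng(seed)
    w0 = rng.lognormal(mean=0.0, sigma=0.5, size=n_hp)
    phi = np.array(
        [-depletion_rate if g in depleted else 0.0 for g in gene_of]
    )

    table = pd.DataFrame(
        {"hairpin_id": hairpins, "gene": gene_of, "is_control": is_control}
    )
    for day in sorted(timepoints):
        w = w0 * 2.0 ** (phi * day / 7.0)
        p = w / w.sum()
        for rep in range(1, n_replicates + 1):
            table[f"d{day}_r{rep}"] = rng.multinomial(int(library_size), p)
    truth = {
        "depleted_genes": sorted(depleted),
        "phi": pd.Series(phi, index=hairpins),
        "baseline_weight": pd.Series(w0, index=hairpins),
    }
    return table, pd.Series(gene_of, index=hairpins), truth
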