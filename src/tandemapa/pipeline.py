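"""End-to-end orchestration: configuration, seeding, staged runs.

A single global seed is fanned out to per-stage child seeds through a
counter-based hash (:func:`stage_seed`), so every stochastic stage (MCMC,
NMF restarts, consensus resampling, simulators) is independently
reproducible from the config alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import changepoint as cp
from . import diffapa, screen, simulate, subtype
from .normalize import IntensityMatrix, normalize_to_normal_median

logger = logging.getLogger(__name__)

_KNOWN_SECTIONS = {
    "seed", "outdir", "inputs", "bcp", "qc", "subtype", "screen", "simulate",
    "diffapa",
}


def stage_seed(global_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic child seed (< 2^31) for a named stage."""
    h = hashlib.sha256(f"{global_seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "tandemapa_out"
    inputs: dict = field(default_factory=dict)
    bcp: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    subtype: dict = field(default_factory=dict)
    screen: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    diffapa: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_SECTIONS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def echo(self, outdir: Path) -> None:
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "config_echo.yaml", "w") as fh:
            yaml.safe_dump(self.__dict__, fh, default_flow_style=False)


def profile_tandems(
    matrix: IntensityMatrix,
    tandems: list[ann.TandemUTR],
    params: cp.BCPParams | None = None,
    peak_frac: float = 0.5,
    stability_ratio: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Change-point + SUI profiling of every tandem against one matrix.

    The matrix must already be normal-median normalized.  Returns
    (SUI matrix restricted to QC-passing tandems, per-tandem QC table).
    """
    params = params or cp.BCPParams()
    sui_rows = {}
    qc_rows = []
    for i, t in enumerate(tandems):
        missing = [p for p in t.probes if p not in matrix.values.index]
        if missing:
            raise ValueError(f"{t.tandem_id}: probes missing from matrix: {missing[:3]}")
        X = matrix.values.loc[t.probes]
        p = cp.BCPParams(
            p0=params.p0, w0=params.w0, burnin=params.burnin, mcmc=params.mcmc,
            seed=stage_seed(seed, "bcp", i),
        )
        res = cp.bcp_multivariate(X, p)
        status = cp.qc_filter(res, peak_frac=peak_frac, stability_ratio=stability_ratio)
        qc_rows.append(
            {
                "tandem_id": t.tandem_id,
                "change_index": res.change_index,
                "max_rho": float(res.rho.max()) if res.rho.size else 0.0,
                "qc_status": status,
            }
        )
        if status == cp.QC_OK:
            sui_rows[t.tandem_id] = cp.compute_sui(res)
    sui = pd.DataFrame(sui_rows).T
    if not sui.empty:
        sui = sui[matrix.sample_ids]
    qc = pd.DataFrame(qc_rows).set_index("tandem_id")
    return sui, qc


def run_simulate(cfg: PipelineConfig) -> Path:
    """Write a synthetic probe dataset and screen count table."""
    outdir = Path(cfg.outdir)
    cfg.echo(outdir)
    sim_kwargs = dict(cfg.simulate)
    screen_kwargs = sim_kwargs.pop("screen", {})
    if "subtype_sizes" in sim_kwargs:
        sim_kwargs["subtype_sizes"] = tuple(sim_kwargs["subtype_sizes"])
    if "probes_per_segment" in sim_kwargs:
        sim_kwargs["probes_per_segment"] = tuple(sim_kwargs["probes_per_segment"])
    config = simulate.SimulationConfig(
        seed=stage_seed(cfg.seed, "simulate"), **sim_kwargs
    )
    matrix, probe_map, annotation, truth = simulate.simulate_probe_dataset(config)
    simulate.write_probe_dataset(outdir, matrix, probe_map, annotation)
    truth.true_sui.to_csv(outdir / "truth_sui.tsv", sep="\t")
    counts, _, _ = simulate.simulate_screen_counts(
        seed=stage_seed(cfg.seed, "screen_sim"),
        **screen_kwargs,
    )
    counts.to_csv(outdir / "screen_counts.tsv", sep="\t", index=False)
    return outdir


def run_profile(cfg: PipelineConfig) -> Path:
    """Chain annotation -> normalization -> change points -> SUI matrix."""
    outdir = Path(cfg.outdir)
    cfg.echo(outdir)
    matrix = IntensityMatrix.read(cfg.inputs["intensity"], cfg.inputs["samples"])
    if not matrix.sample_ids:
        raise ValueError("empty sample sheet")
    probe_map = ann.read_probe_map(cfg.inputs["probes"])
    annotation = pd.read_csv(cfg.inputs["annotation"], sep="\t")
    candidates = ann.identify_tandems(annotation)
    tandems = ann.assign_probes(candidates, probe_map)
    normalized = normalize_to_normal_median(matrix)
    sui, qc = profile_tandems(
        normalized,
        tandems,
        cp.BCPParams(**cfg.bcp),
        seed=cfg.seed,
        **cfg.qc,
    )
    sui.to_csv(outdir / "sui.tsv", sep="\t", index_label="tandem_id")
    qc.to_csv(outdir / "qc.tsv", sep="\t")
    counts = {
        "candidates": len(candidates),
        "probe_filtered": len(tandems),
        **{
            status: int((qc["qc_status"] == status).sum())
            for status in (cp.QC_OK, cp.QC_MULTI_PEAK, cp.QC_UNSTABLE,
                           cp.QC_TOO_FEW_PROBES)
        },
    }
    with open(outdir / "profile_log.json", "w") as fh:
        json.dump(counts, fh, indent=2)
    logger.info("profile stage counts: %s", counts)
    return outdir


def run_diffapa(cfg: PipelineConfig) -> Path:
    """Tumor-vs-normal moderated test with direction calls."""
    outdir = Path(cfg.outdir)
    cfg.echo(outdir)
    sui = pd.read_csv(cfg.inputs["sui"], sep="\t", index_col=0)
    sheet = pd.read_csv(cfg.inputs["samples"], sep="\t", dtype=str)
    groups = sheet.set_index("sample_id")["group"]
    res = diffapa.moderated_two_group_test(sui, groups, group_a="tumor")
    res = diffapa.classify_direction(res, **cfg.diffapa)
    res.to_csv(outdir / "diffapa.tsv", sep="\t")
    summary = {
        "n_tested": int(len(res)),
        "n_shortened": int((res["direction"] == diffapa.SHORTENED).sum()),
        "n_lengthened": int((res["direction"] == diffapa.LENGTHENED).sum()),
    }
    with open(outdir / "diffapa_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return outdir


def run_subtype(cfg: PipelineConfig) -> Path:
    """CV selection -> rank survey -> nsNMF + consensus k-means labels."""
    outdir = Path(cfg.outdir)
    cfg.echo(outdir)
    sui = pd.read_csv(cfg.inputs["sui"], sep="\t", index_col=0)
    sheet = pd.read_csv(cfg.inputs["samples"], sep="\t", dtype=str)
    groups = sheet.set_index("sample_id")["group"]
    tumors = [s for s in sui.columns if groups.get(s) == "tumor"]
    sui_t = sui[tumors]

    opts = dict(cfg.subtype)
    top_fraction = opts.pop("top_fraction", 0.25)
    ranks = opts.pop("ranks", [2, 10])
    survey_runs = opts.pop("survey_runs", 50)
    final_runs = opts.pop("final_runs", 200)
    theta = opts.pop("theta", 0.5)
    consensus_iter = opts.pop("consensus_iter", 1000)
    subsample_frac = opts.pop("subsample_frac", 0.8)
    rank = opts.pop("rank", None)
    if opts:
        raise ValueError(f"unknown subtype options: {sorted(opts)}")

    selected = diffapa.cv_rank_select(sui_t, top_fraction)
    X, scaler = subtype.scale_features(sui_t.loc[selected])

    survey = None
    if rank is None:
        survey = subtype.rank_survey(
            X, ranks=range(int(ranks[0]), int(ranks[1]) + 1), n_runs=survey_runs,
            theta=theta, seed=stage_seed(cfg.seed, "rank_survey"),
        )
        survey.to_csv(outdir / "rank_survey.tsv", sep="\t")
        rank = subtype.select_rank(survey)

    sol = subtype.nsnmf(
        X, int(rank), theta=theta, n_runs=final_runs,
        seed=stage_seed(cfg.seed, "nsnmf_final"),
    )
    C_km, km_labels = subtype.consensus_kmeans(
        X, int(rank), n_iter=consensus_iter, subsample_frac=subsample_frac,
        seed=stage_seed(cfg.seed, "consensus_kmeans"),
    )
    labels = pd.DataFrame(
        {
            "sample_id": tumors,
            "nmf_label": [f"S{l + 1}" for l in sol.labels],
            "consensus_label": [f"S{l + 1}" for l in km_labels],
        }
    )
    labels.to_csv(outdir / "subtype_labels.tsv", sep="\t", index=False)
    np.savetxt(outdir / "consensus_nmf.tsv", sol.consensus, delimiter="\t")
    np.savetxt(outdir / "consensus_kmeans.tsv", C_km, delimiter="\t")
    pca = subtype.pca_coords(sui_t.loc[selected])
    pca.to_csv(outdir / "pca_coords.tsv", sep="\t", index_label="sample_id")
    summary = {
        "rank": int(rank),
        "n_selected_features": len(selected),
        "nmf_divergence": float(sol.divergence),
        "metrics": subtype.consensus_metrics(sol.consensus, int(rank)),
    }
    with open(outdir / "subtype_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return outdir


def run_classify(cfg: PipelineConfig) -> Path:
    """Assign new samples with a serialized shrunken-centroid model."""
    outdir = Path(cfg.outdir)
    cfg.echo(outdir)
    model = subtype.ShrunkenCentroidModel.from_json(cfg.inputs["model"])
    new_sui = pd.read_csv(cfg.inputs["sui"], sep="\t", index_col=0)
    labels, scores = subtype.classify_samples(model, new_sui)
    out = scores.copy()
    out.insert(0, "label", labels)
    out.to_csv(outdir / "classified.tsv", sep="\t", index_label="sample_id")
    return outdir


def run_screen(cfg: PipelineConfig) -> Path:
    """Screen normalization, enrichment, depletion and QC statistics."""
    outdir = Path(cfg.outdir)
    cfg.echo(outdir)
    counts = pd.read_csv(cfg.inputs["screen_counts"], sep="\t")
    opts = dict(cfg.screen)
    pseudocount = opts.pop("pseudocount", 1.0)
    day = opts.pop("day", 21)
    if opts:
        raise ValueError(f"unknown screen options: {sorted(opts)}")
    cpm = screen.normalize_counts(counts)
    hp, gene_scores = screen.enrichment_scores(cpm, pseudocount=pseudocount)
    dep = screen.depletion_test(hp, day=day)
    results = gene_scores.join(dep[["p", "q"]], how="left")
    results.to_csv(outdir / "screen_results.tsv", sep="\t")
    hp.to_csv(outdir / "hairpin_scores.tsv", sep="\t", index=False)
    conc = screen.replicate_concordance(cpm)
    cols = screen.count_columns(cpm)
    d0_col = next(c for d, r, c in cols if d == 0)
    dN_col = next(c for d, r, c in sorted(cols, reverse=True))
    D, p = screen.diversity_shift(cpm[d0_col], cpm[dN_col], pseudocount=pseudocount)
    qc = {
        "replicate_spearman": conc.round(4).to_dict(),
        "diversity_shift": {"columns": [d0_col, dN_col], "D": D, "p": p},
    }
    with open(outdir / "screen_qc.json", "w") as fh:
        json.dump(qc, fh, indent=2)
    return outdir
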