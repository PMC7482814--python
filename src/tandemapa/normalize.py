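"""Probe-level normalizations preceding expression and APA analyses.

All intensities are log2-scale (post-RMA); normalization is therefore
subtraction of reference medians, per sample or per probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"


@dataclass
class IntensityMatrix:
    """Probes x samples log2 intensity matrix with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by probe id, one column per sample, log2 scale.
    sample_groups
        Series mapping sample id -> ``"tumor"`` or ``"normal"``.
    subtypes
        Optional Series mapping tumor sample id -> subtype label.
    """

    values: pd.DataFrame
    sample_groups: pd.Series
    subtypes: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError("intensity matrix contains missing values")
        if not np.isfinite(vals).all():
            raise ValueError("intensity matrix contains non-finite values")
        missing = [s for s in self.values.columns if s not in self.sample_groups.index]
        if missing:
            raise ValueError(f"samples absent from sample sheet: {missing[:5]}")
        bad = set(self.sample_groups.loc[list(self.values.columns)]) - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"unknown sample groups: {sorted(bad)}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def normal_samples(self) -> list[str]:
        g = self.sample_groups.loc[list(self.values.columns)]
        return list(g.index[g == NORMAL])

    @property
    def tumor_samples(self) -> list[str]:
        g = self.sample_groups.loc[list(self.values.columns)]
        return list(g.index[g == TUMOR])

    def with_values(self, values: pd.DataFrame) -> "IntensityMatrix":
        return IntensityMatrix(values, self.sample_groups, self.subtypes)

    @classmethod
    def read(cls, matrix_tsv, sample_sheet_tsv) -> "IntensityMatrix":
        values = pd.read_csv(matrix_tsv, sep="\t", index_col=0)
        sheet = pd.read_csv(sample_sheet_tsv, sep="\t", dtype=str)
        groups = sheet.set_index("sample_id")["group"]
        subtypes = None
        if "subtype" in sheet.columns:
            st = sheet.set_index("sample_id")["subtype"]
            subtypes = st[st.notna() & (st != "NA")]
        return cls(values, groups, subtypes)

    def write(self, matrix_tsv, sample_sheet_tsv=None) -> None:
        self.values.to_csv(matrix_tsv, sep="\t", index_label="probe_id")
        if sample_sheet_tsv is not None:
            sheet = pd.DataFrame({
                "sample_id": self.sample_ids,
                "group": self.sample_groups.loc[self.sample_ids].to_numpy(),
            })
            if self.subtypes is not None:
                sheet["subtype"] = [
                    self.subtypes.get(s, "NA") for s in self.sample_ids
                ]
            else:
                sheet["subtype"] = "NA"
            sheet.to_csv(sample_sheet_tsv, sep="\t", index=False)


def normalize_to_transcript_median(
    matrix: IntensityMatrix, probe_to_transcript: pd.Series
) -> IntensityMatrix:
    """Subtract, per sample, the median intensity of each probe's transcript.

    ``probe_to_transcript`` maps every probe id in the matrix to exactly one
    transcript id.  This is the PLATA-style normalization that removes
    per-sample transcript abundance so that residual probe intensities track
    relative isoform usage.
    """
    unmapped = [p for p in matrix.probe_ids if p not in probe_to_transcript.index]
    if unmapped:
        raise ValueError(f"probes without transcript assignment: {unmapped[:5]}")
    tx = probe_to_transcript.loc[matrix.probe_ids]
    medians = matrix.values.groupby(tx.to_numpy()).transform("median")
    return matrix.with_values(matrix.values - medians)


def normalize_to_normal_median(matrix: IntensityMatrix) -> IntensityMatrix:
    """Subtract, per probe, the median intensity across the normal samples.

    Applied before change-point analysis: after this step a normal-like
    sample has ~0 intensity at every probe and a tumor's extended-region
    probes shift by the log2 change in long-isoform fraction.
    """
    normals = matrix.normal_samples
    if not normals:
        raise ValueError(
            "no normal samples in matrix; supply a reference panel of "
            "normals before change-point analysis"
        )
    ref = matrix.values[normals].median(axis=1)
    return matrix.with_values(matrix.values.sub(ref, axis=0))


def quantile_normalize_to_reference(
    df: pd.DataFrame, reference_quantiles: np.ndarray
) -> pd.DataFrame:
    """Map each column of ``df`` onto a fixed reference distribution.

    ``reference_quantiles`` are sorted reference values (one per feature
    rank).  Each column is replaced by the reference value at its ranks;
    ties receive the mean of the tied reference values.
    """
    ref = np.sort(np.asarray(reference_quantiles, dtype=float))
    if len(ref) != df.shape[0]:
        raise ValueError("reference quantiles length must equal feature count")
    out = {}
    for col in df.columns:
        x = df[col].to_numpy(dtype=float)
        order = np.argsort(x, kind="mergesort")
        mapped = np.empty_like(x)
        mapped[order] = ref
        # average reference values over tied input values
        s = pd.Series(mapped).groupby(pd.Series(x)).transform("mean")
        out[col] = s.to_numpy()
    return pd.DataFrame(out, index=df.index)


def pooled_reference_quantiles(training: pd.DataFrame) -> np.ndarray:
    """Mean-of-sorted-columns reference distribution from training data."""
    sorted_cols = np.sort(training.to_numpy(dtype=float), axis=0)
    return sorted_cols.mean(axis=1)
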