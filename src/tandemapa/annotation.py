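"""Tandem-3'UTR models from transcript annotation and probe maps.

A tandem 3'UTR is a pair of isoforms sharing a 3'UTR start but ending at a
proximal vs a distal polyadenylation site.  Coordinates are genomic, 0-based
half-open (BED convention).  For minus-strand transcripts the annotation
stores breakpoints in transcript orientation (``utr_start`` > ``utr_end``);
the genomic interval is always ``[min, max)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TandemUTR:
    tandem_id: str
    gene_id: str
    chrom: str
    strand: str
    utr_start: int  # shared 3'UTR start (transcript orientation breakpoint)
    proximal_end: int  # proximal APA site
    distal_end: int  # distal APA site
    probes: list[str] = field(default_factory=list)  # transcript 5'->3'
    n_common: int = 0
    n_extended: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.tandem_id}: bad strand {self.strand!r}")
        lo, hi = self.genomic_span
        if not (lo < hi):
            raise ValueError(f"{self.tandem_id}: empty genomic span")
        if self.strand == "+":
            ok = self.utr_start < self.proximal_end < self.distal_end
        else:
            ok = self.utr_start > self.proximal_end > self.distal_end
        if not ok:
            raise ValueError(
                f"{self.tandem_id}: proximal site must lie strictly between "
                "UTR start and distal site in transcript orientation"
            )

    @property
    def genomic_span(self) -> tuple[int, int]:
        return (
            min(self.utr_start, self.distal_end),
            max(self.utr_start, self.distal_end),
        )

    @property
    def n_probes(self) -> int:
        return len(self.probes)


def identify_tandems(annotation: pd.DataFrame) -> list[TandemUTR]:
    """Group transcripts sharing a 3'UTR start into tandem-UTR candidates.

    ``annotation`` has columns gene_id, transcript_id, chrom, strand,
    utr_start, utr_end (one row per transcript; utr_end is the APA site).
    For each (gene, shared start) with >= 2 distinct ends, one candidate is
    emitted with the shortest end as proximal and the longest as distal.
    Genes with a single 3'UTR end yield no candidate.
    """
    required = {"gene_id", "transcript_id", "chrom", "strand", "utr_start", "utr_end"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    for _, row in annotation.iterrows():
        s, e = int(row.utr_start), int(row.utr_end)
        if (row.strand == "+" and e <= s) or (row.strand == "-" and e >= s):
            raise ValueError(
                f"transcript {row.transcript_id}: 3'UTR end {e} not past "
                f"start {s} in transcript orientation ({row.strand})"
            )
    candidates: list[TandemUTR] = []
    for (gene, chrom, strand, start), grp in annotation.groupby(
        ["gene_id", "chrom", "strand", "utr_start"], sort=True
    ):
        ends = sorted(set(int(e) for e in grp["utr_end"]))
        if len(ends) < 2:
            continue
        if strand == "+":
            proximal, distal = ends[0], ends[-1]
        else:
            proximal, distal = ends[-1], ends[0]
        candidates.append(
            TandemUTR(
                tandem_id=f"{gene}:{start}",
                gene_id=str(gene),
                chrom=str(chrom),
                strand=str(strand),
                utr_start=int(start),
                proximal_end=proximal,
                distal_end=distal,
            )
        )
    return candidates


def _contained(p_start, p_end, lo, hi) -> bool:
    return lo <= p_start and p_end <= hi


def assign_probes(
    candidates: list[TandemUTR],
    probe_map: pd.DataFrame,
    min_probes: int = 4,
) -> list[TandemUTR]:
    """Assign uniquely mapped probes to tandems and apply the probe filter.

    Probes whose interval is contained in more than one candidate span are
    dropped entirely; probes with a strand conflicting their tandem are
    dropped with a warning.  Surviving probes are ordered in transcript
    orientation and split at the proximal APA site by the majority of their
    bases (tie -> common).  Tandems with fewer than ``min_probes`` probes in
    either segment are discarded.
    """
    pm = probe_map.reset_index(drop=True)
    p_chrom = pm["chrom"].to_numpy()
    p_start = pm["start"].to_numpy(dtype=int)
    p_end = pm["end"].to_numpy(dtype=int)
    p_strand = pm["strand"].to_numpy()
    p_id = pm["probe_id"].to_numpy()

    # probe -> list of candidate indices whose span contains it
    hits: list[list[int]] = [[] for _ in range(len(pm))]
    for ti, t in enumerate(candidates):
        lo, hi = t.genomic_span
        mask = (p_chrom == t.chrom) & (p_start >= lo) & (p_end <= hi)
        for pi in np.nonzero(mask)[0]:
            hits[pi].append(ti)

    per_tandem: dict[int, list[int]] = {ti: [] for ti in range(len(candidates))}
    for pi, tlist in enumerate(hits):
        if len(tlist) != 1:  # unmapped or multi-mapped: drop
            continue
        ti = tlist[0]
        if p_strand[pi] != candidates[ti].strand:
            warnings.warn(
                f"probe {p_id[pi]} strand conflicts tandem "
                f"{candidates[ti].tandem_id}; dropped"
            )
            continue
        per_tandem[ti].append(pi)

    out: list[TandemUTR] = []
    for ti, t in enumerate(candidates):
        idx = per_tandem[ti]
        if not idx:
            continue
        # transcript orientation: genomic ascending (+) or descending (-)
        idx.sort(key=lambda pi: p_start[pi], reverse=(t.strand == "-"))
        n_common = 0
        probes = []
        for pi in idx:
            if t.strand == "+":
                common_bases = max(
                    0, min(p_end[pi], t.proximal_end) - max(p_start[pi], t.utr_start)
                )
            else:
                common_bases = max(
                    0, min(p_end[pi], t.utr_start) - max(p_start[pi], t.proximal_end)
                )
            ext_bases = (p_end[pi] - p_start[pi]) - common_bases
            if common_bases >= ext_bases:
                n_common += 1
            probes.append(str(p_id[pi]))
        n_extended = len(probes) - n_common
        if n_common < min_probes or n_extended < min_probes:
            continue
        out.append(
            TandemUTR(
                tandem_id=t.tandem_id,
                gene_id=t.gene_id,
                chrom=t.chrom,
                strand=t.strand,
                utr_start=t.utr_start,
                proximal_end=t.proximal_end,
                distal_end=t.distal_end,
                probes=probes,
                n_common=n_common,
                n_extended=n_extended,
            )
        )
    return out


def tandem_table(tandems: list[TandemUTR]) -> pd.DataFrame:
    """Serializable tandem model table (probes semicolon-joined, ordered)."""
    return pd.DataFrame(
        {
            "tandem_id": [t.tandem_id for t in tandems],
            "gene_id": [t.gene_id for t in tandems],
            "strand": [t.strand for t in tandems],
            "n_common": [t.n_common for t in tandems],
            "n_extended": [t.n_extended for t in tandems],
            "probes": [";".join(t.probes) for t in tandems],
        }
    )


def read_probe_map(path) -> pd.DataFrame:
    """Read a BED6 probe map (chrom, start, end, probe_id, score, strand)."""
    return pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "probe_id", "score", "strand"],
    )
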