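"""Gene-annotation parsing and the coordinate contract.

All genomic coordinates inside this package are 0-based, half-open
``[start, end)``. GTF input is 1-based, closed and converted on read; BED
input is consumed as-is. A gene's span is the min/max over its transcripts
and its transcription start sites (TSSs) are the deduplicated set of
transcript starts — the leftmost transcript base on the ``+`` strand, the
rightmost on ``-``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

#: biotype labels used throughout the package
LNCRNA = "lncRNA"
PROTEIN_CODING = "protein_coding"


class AnnotationError(ValueError):
    """Raised for unparseable annotation input (carries the line number)."""


@dataclass(frozen=True)
class GeneModel:
    """A gene with its span, strand, biotype and distinct transcript TSSs."""

    gene_id: str
    name: str
    biotype: str
    chrom: str
    strand: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    tss_list: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: span start must be < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if any(t < self.start or t >= self.end for t in self.tss_list):
            raise ValueError(f"{self.gene_id}: TSS outside gene span")
        if len(set(self.tss_list)) != len(self.tss_list):
            raise ValueError(f"{self.gene_id}: duplicate TSS positions")


@dataclass
class GeneCatalog:
    """Collection of :class:`GeneModel` keyed by gene_id."""

    genes: dict[str, GeneModel]
    annotation_tag: str = ""

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def subset(self, biotype: str) -> "GeneCatalog":
        """Genes of one biotype, as a new catalog."""
        return GeneCatalog(
            {g.gene_id: g for g in self if g.biotype == biotype},
            annotation_tag=self.annotation_tag,
        )


_BIOTYPE_KEYS = ("gene_biotype", "gene_type")


def _attr(feature, key: str) -> str | None:
    vals = feature.attributes.get(key)
    return vals[0] if vals else None


def _biotype(feature) -> str | None:
    for key in _BIOTYPE_KEYS:
        val = _attr(feature, key)
        if val is not None:
            return val
    return None


def read_gene_annotation(
    path: str | Path,
    keep_biotypes: Iterable[str] | None = (LNCRNA, PROTEIN_CODING),
    annotation_tag: str = "",
) -> GeneCatalog:
    """Parse a GTF into a :class:`GeneCatalog`.

    Gene spans are taken as the min/max over the gene's transcripts (the
    ``gene`` record is used only when a gene has no transcript records).
    A TSS is recorded per distinct transcript start. Records without a
    biotype attribute are skipped with a warning; a line the GTF parser
    cannot interpret aborts with its line number.

    Parameters
    ----------
    path
        GTF file; ``gene_biotype`` or ``gene_type`` accepted as the
        biotype attribute key.
    keep_biotypes
        Biotype labels retained in the catalog; ``None`` keeps everything.
    """
    keep = set(keep_biotypes) if keep_biotypes is not None else None
    gene_meta: dict[str, dict] = {}
    tx_bounds: dict[str, list[tuple[int, int]]] = {}

    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                if len(fields) != 9:
                    raise ValueError(f"expected 9 tab-separated fields, got {len(fields)}")
                int(fields[3]), int(fields[4])
                feat = feature_from_line(line)
            except Exception as exc:  # noqa: BLE001 - re-raise with location
                raise AnnotationError(
                    f"{path}: unparseable annotation line {lineno}: {exc}"
                ) from exc
            if feat.featuretype not in ("gene", "transcript"):
                continue
            gene_id = _attr(feat, "gene_id")
            if gene_id is None:
                raise AnnotationError(
                    f"{path}: line {lineno}: record lacks gene_id"
                )
            biotype = _biotype(feat)
            if biotype is None:
                warnings.warn(
                    f"{path}: line {lineno}: gene {gene_id} has no biotype "
                    "attribute; record excluded",
                    stacklevel=2,
                )
                continue
            start0, end0 = feat.start - 1, feat.end  # 1-based closed -> half-open
            if feat.featuretype == "gene":
                gene_meta.setdefault(gene_id, {})
                gene_meta[gene_id].update(
                    name=_attr(feat, "gene_name") or gene_id,
                    biotype=biotype,
                    chrom=feat.seqid,
                    strand=feat.strand,
                    gene_span=(start0, end0),
                )
            else:
                meta = gene_meta.setdefault(gene_id, {})
                if meta.get("name") is None:
                    meta["name"] = _attr(feat, "gene_name") or gene_id
                meta.setdefault("biotype", biotype)
                meta.setdefault("chrom", feat.seqid)
                meta.setdefault("strand", feat.strand)
                tx_bounds.setdefault(gene_id, []).append((start0, end0))

    genes: dict[str, GeneModel] = {}
    for gene_id, meta in gene_meta.items():
        if keep is not None and meta.get("biotype") not in keep:
            continue
        bounds = tx_bounds.get(gene_id)
        if bounds:
            span = (min(s for s, _ in bounds), max(e for _, e in bounds))
        elif "gene_span" in meta:
            span = meta["gene_span"]
            bounds = [span]
        else:  # pragma: no cover - gene_meta entries always have one of the two
            continue
        if meta["strand"] == "+":
            tss = sorted({s for s, _ in bounds})
        else:
            tss = sorted({e - 1 for _, e in bounds})
        genes[gene_id] = GeneModel(
            gene_id=gene_id,
            name=meta["name"],
            biotype=meta["biotype"],
            chrom=meta["chrom"],
            strand=meta["strand"],
            start=span[0],
            end=span[1],
            tss_list=tuple(tss),
        )
    return GeneCatalog(genes, annotation_tag=annotation_tag or str(path))


def extract_tss_windows(
    catalog: GeneCatalog, half_width: int
) -> dict[str, list[tuple[int, int]]]:
    """Per-gene TSS windows ``[tss - w, tss + w + 1)``, clamped at 0.

    A position p is inside a window iff ``|p - tss| <= half_width``; windows
    of one gene may overlap and are deliberately not merged.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    return {
        g.gene_id: [
            (max(0, t - half_width), t + half_width + 1) for t in g.tss_list
        ]
        for g in catalog
    }


# -- tabular round-trip -------------------------------------------------------

_TABLE_COLS = ["gene_id", "name", "biotype", "chrom", "start", "end", "strand", "tss_csv"]


def write_gene_table(catalog: GeneCatalog, path: str | Path) -> None:
    rows = [
        (
            g.gene_id,
            g.name,
            g.biotype,
            g.chrom,
            g.start,
            g.end,
            g.strand,
            ",".join(str(t) for t in g.tss_list),
        )
        for g in catalog
    ]
    pd.DataFrame(rows, columns=_TABLE_COLS).to_csv(path, sep="\t", index=False)


def read_gene_table(path: str | Path) -> GeneCatalog:
    df = pd.read_csv(path, sep="\t", dtype={"tss_csv": str})
    genes = {}
    for row in df.itertuples(index=False):
        tss = tuple(int(t) for t in str(row.tss_csv).split(",")) if row.tss_csv else ()
        genes[row.gene_id] = GeneModel(
            gene_id=row.gene_id,
            name=row.name,
            biotype=row.biotype,
            chrom=row.chrom,
            strand=row.strand,
            start=int(row.start),
            end=int(row.end),
            tss_list=tss,
        )
    return GeneCatalog(genes, annotation_tag=str(path))
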