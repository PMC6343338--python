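"""Site/gene filtering and poly(A)-site quantification.

Filtering removes weakly supported sites (default: fewer than 5 supporting
reads over all samples) and genes left with a single site — a gene must have
at least two sites for its site block to carry usage information.  An
optional gene list restricts the analysis to externally selected genes
(e.g. genes with differentially used sites from an external test).

Quantification is either ``abundance`` (values as-is) or ``relative``: each
site's value divided by the summed value of all sites of its gene in that
sample, the per-sample site-usage proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import EmptyResultError, PacDataset, ValidationError

__all__ = ["FilterReport", "filter_sites", "quantify"]


@dataclass
class FilterReport:
    n_sites_in: int
    n_sites_removed_low_abundance: int
    n_genes_removed_single_site: int
    n_genes_removed_not_selected: int
    n_sites_out: int
    n_genes_out: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def filter_sites(
    data: PacDataset,
    min_reads: float = 5,
    gene_list: set[str] | None = None,
) -> tuple[PacDataset, FilterReport]:
    """Remove low-abundance sites, then single-site genes, then unselected genes.

    A site is low-abundance when its total count over all samples is below
    ``min_reads``.  Site order is preserved.  Raises
    :class:`~apacca.datamodel.EmptyResultError` (report attached) if no gene
    survives.
    """
    if data.quantification != "raw":
        raise ValidationError("filter_sites expects raw counts")
    n_in = data.n_sites
    totals = data.counts.sum(axis=1)
    keep_site = totals >= min_reads
    n_low = int(np.sum(~keep_site))

    kept = data.subset_sites(np.flatnonzero(keep_site))

    # genes reduced to <2 sites are dropped entirely
    gr = kept.gene_rows
    multi = {g for g, rows in gr.items() if len(rows) >= 2}
    n_single_site_genes = len(gr) - len(multi)
    rows = [i for i, s in enumerate(kept.sites) if s.gene_id in multi]
    kept = kept.subset_sites(rows)

    n_not_selected = 0
    if gene_list is not None:
        before = set(kept.gene_rows)
        selected = before & set(gene_list)
        n_not_selected = len(before) - len(selected)
        rows = [i for i, s in enumerate(kept.sites) if s.gene_id in selected]
        kept = kept.subset_sites(rows)

    report = FilterReport(
        n_sites_in=n_in,
        n_sites_removed_low_abundance=n_low,
        n_genes_removed_single_site=n_single_site_genes,
        n_genes_removed_not_selected=n_not_selected,
        n_sites_out=kept.n_sites,
        n_genes_out=len(kept.gene_rows),
    )
    if report.n_genes_out == 0:
        raise EmptyResultError("filtering removed every gene", report=report)
    return kept, report


def quantify(data: PacDataset, mode: str) -> PacDataset:
    """Quantify sites by ``abundance`` (identity) or ``relative`` usage.

    Relative usage: per gene and sample, ``a(p) / sum_i a(i)`` over the
    gene's sites; a gene with zero total in a sample gets all-zero usage
    (not NaN), keeping downstream variances finite.
    """
    if mode not in ("abundance", "relative"):
        raise ValidationError(f"unknown quantification mode {mode!r}")
    if mode == "abundance":
        return PacDataset(
            sites=list(data.sites),
            counts=data.counts.copy(),
            design=data.design,
            quantification="abundance",
        )
    values = data.counts.copy()
    for rows in data.gene_rows.values():
        tot = values[rows].sum(axis=0)
        nz = tot > 0
        values[np.ix_(rows, np.flatnonzero(nz))] /= tot[nz]
        values[np.ix_(rows, np.flatnonzero(~nz))] = 0.0
    return PacDataset(
        sites=list(data.sites),
        counts=values,
        design=data.design,
        quantification="relative",
    )
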