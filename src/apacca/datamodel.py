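"""Core containers for poly(A)-site count data with a replicated design.

A PAC (poly(A)-site count) dataset is a site x sample matrix together with a
site -> gene mapping and an experimental design: ``T`` experiments
(conditions, tissues, developmental stages ...), the ``t``-th measured with
``R(t)`` biological replicates, ``R = sum_t R(t)`` samples in total.  Genes
are represented by the block of rows belonging to their sites, so one gene
carries a multivariate profile rather than a single expression value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ApaccaError",
    "ValidationError",
    "DesignMismatchError",
    "EmptyResultError",
    "SiteRecord",
    "ExperimentDesign",
    "PacDataset",
]


class ApaccaError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(ApaccaError):
    """Input violates a structural contract (shape, sign, uniqueness)."""


class DesignMismatchError(ValidationError):
    """Count columns and the sample sheet do not describe the same samples."""


class EmptyResultError(ApaccaError):
    """An operation removed every gene; carries the filter report if any."""

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report


@dataclass(frozen=True)
class SiteRecord:
    """One poly(A) site: identifier, host gene, optional genomic coordinates.

    Coordinates are 1-based inclusive and are carried through for export but
    never used in any computation.
    """

    site_id: str
    gene_id: str
    chrom: str | None = None
    strand: str | None = None
    position: int | None = None

    def __post_init__(self):
        if self.strand not in (None, "+", "-"):
            raise ValidationError(
                f"strand of site {self.site_id!r} must be '+' or '-', got {self.strand!r}"
            )


@dataclass(frozen=True)
class ExperimentDesign:
    """T experiments with R(t) replicates each; sample order is fixed.

    Parameters
    ----------
    experiments
        Ordered experiment labels, length ``T >= 2``.
    samples
        Ordered ``(sample_id, experiment, replicate_index)`` triples, one per
        count column.  Replicate indices within an experiment must be
        ``1..R(t)`` with no gaps.
    """

    experiments: tuple[str, ...]
    samples: tuple[tuple[str, str, int], ...]

    def __post_init__(self):
        if len(self.experiments) < 2:
            raise ValidationError("a design needs at least 2 experiments")
        if len(set(self.experiments)) != len(self.experiments):
            raise ValidationError("duplicate experiment labels")
        ids = [s[0] for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample ids")
        known = set(self.experiments)
        reps: dict[str, list[int]] = {e: [] for e in self.experiments}
        for sid, exp, rep in self.samples:
            if exp not in known:
                raise ValidationError(f"sample {sid!r} references unknown experiment {exp!r}")
            reps[exp].append(int(rep))
        for exp, rr in reps.items():
            if not rr:
                raise ValidationError(f"experiment {exp!r} has no samples")
            if sorted(rr) != list(range(1, len(rr) + 1)):
                raise ValidationError(
                    f"replicate indices of experiment {exp!r} must be 1..R(t) with no gaps, got {sorted(rr)}"
                )

    @property
    def n_experiments(self) -> int:
        """T."""
        return len(self.experiments)

    @property
    def n_samples(self) -> int:
        """R = sum_t R(t)."""
        return len(self.samples)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(s[0] for s in self.samples)

    @property
    def replicates_of(self) -> dict[str, int]:
        """Experiment label -> R(t)."""
        out = {e: 0 for e in self.experiments}
        for _, exp, _ in self.samples:
            out[exp] += 1
        return out

    def columns_of(self, experiment: str) -> np.ndarray:
        """Column indices of the replicates of one experiment, replicate order."""
        cols = [
            (rep, i)
            for i, (_, exp, rep) in enumerate(self.samples)
            if exp == experiment
        ]
        if not cols:
            raise ValidationError(f"unknown experiment {experiment!r}")
        return np.array([i for _, i in sorted(cols)], dtype=int)

    def drop_experiment(self, experiment: str) -> "ExperimentDesign":
        """Design with one experiment (and all its replicates) removed."""
        if experiment not in self.experiments:
            raise ValidationError(f"unknown experiment {experiment!r}")
        return ExperimentDesign(
            experiments=tuple(e for e in self.experiments if e != experiment),
            samples=tuple(s for s in self.samples if s[1] != experiment),
        )


@dataclass
class PacDataset:
    """Poly(A)-site count matrix with gene mapping and experimental design.

    ``counts`` is non-negative, one row per site, one column per design
    sample.  ``quantification`` records what the values mean: ``raw`` counts,
    ``abundance`` (values used as-is), or ``relative`` (per gene and sample,
    site values sum to 1 or are all 0 for a gene with no reads).
    """

    sites: list[SiteRecord]
    counts: np.ndarray
    design: ExperimentDesign
    quantification: str = "raw"

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.sites), self.design.n_samples):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sites)} sites x {self.design.n_samples} samples"
            )
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("counts must be finite")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate site ids")
        if self.quantification not in ("raw", "abundance", "relative"):
            raise ValidationError(f"unknown quantification {self.quantification!r}")
        if self.quantification == "relative":
            for rows in self.gene_rows.values():
                tot = self.counts[rows].sum(axis=0)
                ok = np.isclose(tot, 1.0, atol=1e-9) | np.isclose(tot, 0.0, atol=1e-9)
                if not np.all(ok):
                    raise ValidationError("relative values must sum to 1 (or 0) per gene and sample")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def gene_rows(self) -> dict[str, np.ndarray]:
        """Gene -> row indices of its sites, in first-appearance gene order."""
        out: dict[str, list[int]] = {}
        for i, s in enumerate(self.sites):
            out.setdefault(s.gene_id, []).append(i)
        return {g: np.array(rows, dtype=int) for g, rows in out.items()}

    @property
    def genes(self) -> list[str]:
        """Gene ids in first-appearance order."""
        return list(self.gene_rows)

    def subset_sites(self, rows: Sequence[int]) -> "PacDataset":
        rows = np.asarray(rows, dtype=int)
        return PacDataset(
            sites=[self.sites[i] for i in rows],
            counts=self.counts[rows],
            design=self.design,
            quantification=self.quantification,
        )

    def drop_experiment(self, experiment: str) -> "PacDataset":
        """Remove one experiment's columns (used by stability validation)."""
        design = self.design.drop_experiment(experiment)
        keep = [i for i, (_, exp, _) in enumerate(self.design.samples) if exp != experiment]
        return PacDataset(
            sites=list(self.sites),
            counts=self.counts[:, keep],
            design=design,
            quantification=self.quantification,
        )

    def gene_totals(self) -> tuple[list[str], np.ndarray]:
        """Per-gene summed site values, one row per gene (gene-level profile)."""
        gr = self.gene_rows
        mat = np.vstack([self.counts[rows].sum(axis=0) for rows in gr.values()])
        return list(gr), mat
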