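"""Tissue-enrichment scoring against a multi-tissue expression compendium.

A gene is called enriched in a target tissue when its mean expression over the
target-tissue libraries sits more than ``threshold`` background standard
deviations above the background mean:

    z = (mean(tissue libraries) - mean(background)) / sd(background)

with the background formed by every library not labelled with the target
tissue (self-exclusion avoids contaminating the background with the signal
being tested; pass ``include_target_in_background=True`` to reproduce a
pooled background).  The default threshold of 5 is deliberately stringent:
it is meant to isolate a small core of genes whose expression is a signature
of the tissue, not merely elevated in it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_Z_THRESHOLD = 5.0


@dataclass
class TissueCompendium:
    """Genes x libraries expression matrix with a tissue label per library."""

    values: pd.DataFrame  # genes x libraries
    tissue_of_library: pd.Series  # library id -> tissue label

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in compendium")
        unlabelled = [c for c in self.values.columns if c not in self.tissue_of_library.index]
        if unlabelled:
            raise ValueError(f"libraries missing a tissue label: {unlabelled}")
        self.tissue_of_library = self.tissue_of_library.loc[list(self.values.columns)]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.values.columns)

    def libraries_of(self, tissue: str) -> list[str]:
        return list(self.tissue_of_library.index[self.tissue_of_library == tissue])


@dataclass
class EnrichmentScore:
    gene_id: str
    tissue_mean: float
    background_mean: float
    background_sd: float
    z: float  # NaN when background_sd == 0
    enriched: bool


def read_compendium(matrix_path, tissue_path) -> TissueCompendium:
    values = pd.read_csv(matrix_path, index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    tissues = pd.read_csv(tissue_path, index_col=0).iloc[:, 0].astype(str)
    tissues.index = tissues.index.astype(str)
    return TissueCompendium(values.astype(float), tissues)


def write_compendium(c: TissueCompendium, matrix_path, tissue_path) -> None:
    c.values.to_csv(matrix_path, index_label="gene_id")
    c.tissue_of_library.rename("tissue").to_csv(tissue_path, index_label="library_id")


def enrichment_z(
    c: TissueCompendium,
    tissue: str,
    threshold: float = DEFAULT_Z_THRESHOLD,
    include_target_in_background: bool = False,
) -> list[EnrichmentScore]:
    """Score every gene for enrichment in ``tissue`` against the rest of the
    compendium.  Background sd uses the n-1 denominator; a gene with zero
    background sd gets an undefined (NaN) z, enriched=False, and a warning.
    """
    target_libs = c.libraries_of(tissue)
    if not target_libs:
        raise ValueError(f"tissue {tissue!r} not present in compendium")
    if include_target_in_background:
        bg_libs = c.library_ids
    else:
        bg_libs = [l for l in c.library_ids if l not in set(target_libs)]
    if len(bg_libs) < 2:
        raise ValueError("need >= 2 background libraries for a defined sd")

    tmean = c.values[target_libs].mean(axis=1)
    bmean = c.values[bg_libs].mean(axis=1)
    bsd = c.values[bg_libs].std(axis=1, ddof=1)

    scores: list[EnrichmentScore] = []
    for gid in c.gene_ids:
        sd = float(bsd[gid])
        if sd == 0:
            logger.warning("enrichment_z: zero background sd for gene %r; z undefined", gid)
            z = math.nan
            enr = False
        else:
            z = float((tmean[gid] - bmean[gid]) / sd)
            enr = z > threshold
        scores.append(EnrichmentScore(str(gid), float(tmean[gid]), float(bmean[gid]), sd, z, enr))
    return scores


def filter_enriched(scores: list[EnrichmentScore], threshold: float = DEFAULT_Z_THRESHOLD) -> list[str]:
    """Gene ids with z strictly greater than ``threshold``, sorted by
    descending z (ties by id for reproducibility)."""
    hits = [s for s in scores if not math.isnan(s.z) and s.z > threshold]
    hits.sort(key=lambda s: (-s.z, s.gene_id))
    return [s.gene_id for s in hits]


def write_scores(scores: list[EnrichmentScore], path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "tissue_mean": s.tissue_mean,
                "background_mean": s.background_mean,
                "background_sd": s.background_sd,
                "z": s.z,
                "enriched": s.enriched,
            }
            for s in scores
        ]
    ).to_csv(path, index=False)


def write_enriched_list(ids: list[str], path) -> None:
    with open(path, "w") as fh:
        for gid in ids:
            fh.write(f"{gid}\n")
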