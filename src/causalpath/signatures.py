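"""Transcriptomic signatures: fold-change tables, binarization, KG coverage.

A drug-perturbation or disease experiment is reduced to per-gene calls in
{-1, 0, +1}: down-regulated, measured-but-unchanged, up-regulated.  Genes
absent from a signature are *unmeasured*, which is semantically distinct from
a measured 0 — the reasoning layer decides how each is scored inside a path.
Gene identifiers are expected to be the same strings as the KG's protein node
ids (ENTREZ-style harmonization happens upstream of this package).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .kg import CausalKG, NodeKind

__all__ = [
    "SignatureContext",
    "FoldChangeTable",
    "Signature",
    "CoverageRecord",
    "binarize",
    "load_signature",
    "load_manifest",
    "kg_coverage",
]

DEFAULT_FC_CUTOFF = 1.0


class SignatureContext(str, enum.Enum):
    DRUG = "drug"
    DISEASE = "disease"


@dataclass
class FoldChangeTable:
    """Per-gene log2 fold changes (with optional p-values) for one experiment."""

    log2fc: dict[str, float]
    context: SignatureContext
    context_id: str
    p_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.context = SignatureContext(self.context)
        for g, v in self.log2fc.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite log2fc for gene {g!r}: {v}")


@dataclass
class Signature:
    """Binarized per-gene calls for one drug or disease experiment.

    ``values`` maps gene id -> {-1, 0, +1}; genes missing from the mapping are
    unmeasured.
    """

    values: dict[str, int]
    context: SignatureContext
    context_id: str
    cutoff_used: float = DEFAULT_FC_CUTOFF

    def __post_init__(self):
        self.context = SignatureContext(self.context)
        bad = {g: v for g, v in self.values.items() if v not in (-1, 0, 1)}
        if bad:
            raise ValueError(f"signature values outside {{-1,0,+1}}: {bad}")

    def get(self, gene: str) -> Optional[int]:
        """The call for a gene, or None when unmeasured."""
        return self.values.get(gene)


def binarize(
    table: FoldChangeTable,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    p_threshold: Optional[float] = None,
) -> Signature:
    """Threshold fold changes into {-1, 0, +1} calls.

    A gene is called +1 when ``log2fc >= fc_cutoff`` and -1 when
    ``log2fc <= -fc_cutoff`` (ties at the cutoff are called dysregulated);
    otherwise 0.  When ``p_threshold`` is given, a dysregulated call
    additionally requires the gene's p-value (where available) to be at or
    below the threshold; by default no p-value filter is applied.
    """
    if fc_cutoff < 0:
        raise ValueError(f"fc_cutoff must be >= 0, got {fc_cutoff}")
    if p_threshold is not None and not 0 < p_threshold <= 1:
        raise ValueError(f"p_threshold must be in (0, 1], got {p_threshold}")
    values: dict[str, int] = {}
    for gene, fc in table.log2fc.items():
        if fc >= fc_cutoff and fc != 0:
            call = 1
        elif fc <= -fc_cutoff and fc != 0:
            call = -1
        else:
            call = 0
        if call != 0 and p_threshold is not None:
            p = table.p_values.get(gene)
            if p is not None and p > p_threshold:
                call = 0
        values[gene] = call
    return Signature(values, table.context, table.context_id, cutoff_used=fc_cutoff)


def load_signature(
    path: str | Path,
    context: SignatureContext | str,
    context_id: str,
) -> Union[FoldChangeTable, Signature]:
    """Read one signature TSV.

    Accepted layouts: ``gene_id  log2fc [p_value]`` (returns a
    :class:`FoldChangeTable` to be binarized) or ``gene_id  binary`` with
    values in {-1, 0, 1} (returns a ready :class:`Signature`, the pre-binarized
    case).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'gene_id'")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate gene id(s): {sorted(set(dup))}")
    genes = df["gene_id"].tolist()
    if "binary" in df.columns:
        vals = pd.to_numeric(df["binary"], errors="raise")
        bad = sorted(set(vals) - {-1, 0, 1})
        if bad:
            raise ValueError(f"{path}: binary values outside {{-1,0,1}}: {bad}")
        return Signature(dict(zip(genes, vals.astype(int))), context, context_id)
    if "log2fc" in df.columns:
        fc = pd.to_numeric(df["log2fc"], errors="raise").astype(float)
        p_values: dict[str, float] = {}
        if "p_value" in df.columns:
            pv = pd.to_numeric(df["p_value"], errors="raise").astype(float)
            p_values = {
                g: p for g, p in zip(genes, pv) if not math.isnan(p)
            }
        return FoldChangeTable(dict(zip(genes, fc)), context, context_id, p_values)
    raise ValueError(f"{path}: expected a 'log2fc' or 'binary' column")


def load_manifest(
    path: str | Path,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    p_threshold: Optional[float] = None,
) -> dict[str, Signature]:
    """Read a manifest TSV (``context_id  path  context``) into signatures.

    Relative signature paths are resolved against the manifest's directory.
    Fold-change files are binarized with ``fc_cutoff``; pre-binarized files
    are taken verbatim.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"context_id", "path", "context"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: manifest needs columns {sorted(required)}")
    out: dict[str, Signature] = {}
    for row in df.itertuples(index=False):
        if row.context_id in out:
            raise ValueError(f"{path}: duplicate context_id {row.context_id!r}")
        sig_path = Path(row.path)
        if not sig_path.is_absolute():
            sig_path = path.parent / sig_path
        loaded = load_signature(sig_path, row.context, row.context_id)
        if isinstance(loaded, FoldChangeTable):
            loaded = binarize(loaded, fc_cutoff=fc_cutoff, p_threshold=p_threshold)
        out[row.context_id] = loaded
    return out


@dataclass
class CoverageRecord:
    """Overlap between a signature and a KG's protein nodes."""

    n_proteins: int
    n_measured: int
    n_dysregulated: int
    n_unmeasured: int

    @property
    def frac_measured(self) -> float:
        return self.n_measured / self.n_proteins if self.n_proteins else 0.0

    @property
    def frac_dysregulated(self) -> float:
        return self.n_dysregulated / self.n_proteins if self.n_proteins else 0.0

    @property
    def frac_unmeasured(self) -> float:
        return self.n_unmeasured / self.n_proteins if self.n_proteins else 0.0


def kg_coverage(sig: Signature, kg: CausalKG) -> CoverageRecord:
    """How many of the KG's protein nodes the signature measures / dysregulates."""
    proteins = kg.nodes(NodeKind.PROTEIN)
    measured = [p for p in proteins if p in sig.values]
    dysregulated = [p for p in measured if sig.values[p] != 0]
    return CoverageRecord(
        n_proteins=len(proteins),
        n_measured=len(measured),
        n_dysregulated=len(dysregulated),
        n_unmeasured=len(proteins) - len(measured),
    )
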