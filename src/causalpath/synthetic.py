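"""Synthetic benchmark generator: random typed signed KGs with planted
drug→protein→…→disease mechanisms and matching signatures.

The generator emulates the statistical shape of the real inputs — a sparse
causal knowledge graph, per-experiment binarized expression signatures with
noise and missing genes, and a positive-label list — while recording exact
ground truth, so that every claim of the reasoning layer can be tested
without external downloads.

Construction: a background KG is sampled stratum by stratum (chemical→protein,
protein→protein, protein→disease edges drawn independently with per-stratum
densities, each inhibitory with a configurable probability).  For each
planted (chemical, disease) pair one guaranteed causal path of fixed length
is inserted whose cumulative effect on the disease is inhibitory; the
chemical's signature gets each on-path protein's inferred regulation, the
disease's signature its negation.  Planted values are then degraded by noise
(sign flips and/or zeroing) and missingness; off-path measured proteins
receive background calls drawn i.i.d. from a three-point distribution.
Planted paths use disjoint protein sets so a chemical or disease shared by
two planted pairs never receives contradictory values.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .evaluation import LabelSet
from .kg import CausalKG, NodeKind, write_kg
from .signatures import Signature, SignatureContext

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "Benchmark",
    "generate_benchmark",
    "write_benchmark",
    "worked_fixture",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic benchmark.

    Defaults describe a small but non-trivial study: 10 chemicals, 60
    proteins and 5 diseases with sparse strata (mean ~3 protein targets per
    chemical, ~1.8 outgoing protein-protein edges per protein, ~3 disease
    edges per disease), half of all edges inhibitory, five planted mechanisms
    of length 4, and clean signatures (no noise, no missingness) whose
    off-path background calls are ±1 with probability 0.15 each —
    loosely emulating the dysregulation call rate of a |log2FC| >= 1 cutoff.
    """

    n_chemicals: int = 10
    n_proteins: int = 60
    n_diseases: int = 5
    p_chem_prot: float = 0.05
    p_prot_prot: float = 0.03
    p_prot_dis: float = 0.05
    inhibition_fraction: float = 0.5
    n_planted_pairs: int = 5
    planted_path_length: int = 4
    signature_noise: float = 0.0
    noise_mode: Literal["both", "flip", "zero"] = "both"
    missingness: float = 0.0
    background_probs: tuple[float, float, float] = (0.15, 0.70, 0.15)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_chemicals", "n_proteins", "n_diseases"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("p_chem_prot", "p_prot_prot", "p_prot_dis"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        for name in ("inhibition_fraction", "signature_noise"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness must be in [0, 1)")
        if self.planted_path_length < 2:
            raise ValueError("planted_path_length must be >= 2")
        if self.n_planted_pairs < 0:
            raise ValueError("n_planted_pairs must be >= 0")
        if self.n_planted_pairs > self.n_chemicals * self.n_diseases:
            raise ValueError("more planted pairs than chemical x disease combinations")
        if self.n_planted_pairs * (self.planted_path_length - 1) > self.n_proteins:
            raise ValueError(
                "not enough proteins for disjoint planted paths: need "
                f"{self.n_planted_pairs * (self.planted_path_length - 1)}"
            )
        if abs(sum(self.background_probs) - 1.0) > 1e-9:
            raise ValueError("background_probs must sum to 1")
        if self.noise_mode not in ("both", "flip", "zero"):
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator."""

    planted_positive_pairs: set[tuple[str, str]]
    planted_paths: dict[tuple[str, str], dict]
    decoy_pairs: set[tuple[str, str]]
    spec: SyntheticSpec
    emitted_stratum_counts: dict[str, int] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "planted_positive_pairs": sorted(map(list, self.planted_positive_pairs)),
            "planted_paths": {
                f"{a}||{b}": desc for (a, b), desc in sorted(self.planted_paths.items())
            },
            "decoy_pairs": sorted(map(list, self.decoy_pairs)),
            "spec": dataclasses.asdict(self.spec),
            "emitted_stratum_counts": self.emitted_stratum_counts,
        }


@dataclass
class Benchmark:
    """A complete generated study: KG, signatures, labels and truth."""

    kg: CausalKG
    drug_signatures: dict[str, Signature]
    disease_signatures: dict[str, Signature]
    labels: LabelSet
    truth: SyntheticTruth


def _sample_stratum(
    rng: np.random.Generator,
    sources: list[str],
    targets: list[str],
    density: float,
    inhibition_fraction: float,
    allow_self: bool = False,
) -> list[tuple[str, str, int]]:
    edges = []
    for s in sources:
        draws = rng.random(len(targets))
        signs = np.where(rng.random(len(targets)) < inhibition_fraction, -1, 1)
        for t, u, sign in zip(targets, draws, signs):
            if not allow_self and s == t:
                continue
            if u < density:
                edges.append((s, t, int(sign)))
    return edges


def generate_benchmark(spec: SyntheticSpec) -> Benchmark:
    """Build a reproducible planted-mechanism benchmark from a spec.

    Every chemical and disease receives one signature; labels are exactly the
    planted pairs; decoys are all remaining chemical x disease combinations.
    Identical specs (including seed) yield identical benchmarks.
    """
    rng = np.random.default_rng(spec.seed)
    chemicals = [f"chem:C{i:03d}" for i in range(spec.n_chemicals)]
    proteins = [f"prot:P{i:04d}" for i in range(spec.n_proteins)]
    diseases = [f"dis:D{i:03d}" for i in range(spec.n_diseases)]

    kg = CausalKG()
    for c in chemicals:
        kg.add_node(c, NodeKind.CHEMICAL)
    for p in proteins:
        kg.add_node(p, NodeKind.PROTEIN)
    for d in diseases:
        kg.add_node(d, NodeKind.DISEASE)

    stratum_counts = {"chemical->protein": 0, "protein->protein": 0, "protein->disease": 0}
    for name, edges in [
        (
            "chemical->protein",
            _sample_stratum(rng, chemicals, proteins, spec.p_chem_prot, spec.inhibition_fraction),
        ),
        (
            "protein->protein",
            _sample_stratum(rng, proteins, proteins, spec.p_prot_prot, spec.inhibition_fraction),
        ),
        (
            "protein->disease",
            _sample_stratum(rng, proteins, diseases, spec.p_prot_dis, spec.inhibition_fraction),
        ),
    ]:
        for s, t, sign in edges:
            if kg.add_edge(s, t, sign, provenance="background"):
                stratum_counts[name] += 1

    # -- plant mechanisms -------------------------------------------------
    combos = [(c, d) for c in chemicals for d in diseases]
    planted_idx = rng.choice(len(combos), size=spec.n_planted_pairs, replace=False)
    planted_pairs = [combos[i] for i in sorted(planted_idx)]
    free_proteins = list(proteins)
    planted_paths: dict[tuple[str, str], dict] = {}
    # clean (pre-noise) planted calls, per context id
    drug_truth: dict[str, dict[str, int]] = {c: {} for c in chemicals}
    disease_truth: dict[str, dict[str, int]] = {d: {} for d in diseases}
    on_path: dict[str, set[str]] = {cid: set() for cid in chemicals + diseases}

    for chem, dis in planted_pairs:
        k = spec.planted_path_length - 1
        pick = rng.choice(len(free_proteins), size=k, replace=False)
        path_proteins = [free_proteins[i] for i in sorted(pick)]
        for p in sorted(path_proteins, reverse=True):
            free_proteins.remove(p)
        signs = [int(s) for s in rng.choice([1, -1], size=spec.planted_path_length)]
        product = int(np.prod(signs))
        if product != -1:  # net effect on the disease must be inhibitory
            signs[-1] *= -1
        nodes = [chem] + path_proteins + [dis]
        running = 1
        regs = {}
        for i, sign in enumerate(signs):
            running *= sign
            if i < len(signs) - 1:  # all but the final (disease) hop
                regs[path_proteins[i]] = running
        for i, sign in enumerate(signs):
            kg.add_edge(nodes[i], nodes[i + 1], sign, provenance="planted")
        for p, r in regs.items():
            drug_truth[chem][p] = r
            disease_truth[dis][p] = -r
            on_path[chem].add(p)
            on_path[dis].add(p)
        planted_paths[(chem, dis)] = {
            "nodes": nodes,
            "edge_signs": signs,
            "inferred_regulation": regs,
        }

    # -- signatures --------------------------------------------------------
    def build_signature(context: SignatureContext, cid: str, clean: dict[str, int]) -> Signature:
        values: dict[str, int] = {}
        bg = rng.choice([1, 0, -1], size=len(proteins), p=[spec.background_probs[0],
                                                           spec.background_probs[1],
                                                           spec.background_probs[2]])
        noise_draws = rng.random(len(proteins))
        mode_draws = rng.random(len(proteins))
        missing_draws = rng.random(len(proteins))
        for i, p in enumerate(proteins):
            if p in clean:
                v = clean[p]
                if noise_draws[i] < spec.signature_noise:
                    if spec.noise_mode == "flip" or (
                        spec.noise_mode == "both" and mode_draws[i] < 0.5
                    ):
                        v = -v
                    else:
                        v = 0
            else:
                v = int(bg[i])
            if missing_draws[i] < spec.missingness:
                continue  # unmeasured
            values[p] = v
        return Signature(values, context, cid)

    drug_signatures = {
        c: build_signature(SignatureContext.DRUG, c, drug_truth[c]) for c in chemicals
    }
    disease_signatures = {
        d: build_signature(SignatureContext.DISEASE, d, disease_truth[d]) for d in diseases
    }

    planted_set = set(planted_pairs)
    truth = SyntheticTruth(
        planted_positive_pairs=planted_set,
        planted_paths=planted_paths,
        decoy_pairs=set(combos) - planted_set,
        spec=spec,
        emitted_stratum_counts=stratum_counts,
    )
    labels = LabelSet(set(planted_set), provenance="synthetic planted mechanisms")
    return Benchmark(kg, drug_signatures, disease_signatures, labels, truth)


def write_benchmark(benchmark: Benchmark, outdir: str | Path) -> dict[str, Path]:
    """Emit a benchmark as the on-disk formats the tool consumes.

    Writes ``kg.tsv``, one signature TSV per experiment, drug and disease
    manifests, ``labels.tsv`` and ``truth.json``; returns the path map.
    Output is deterministic given the benchmark.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    kg_path = outdir / "kg.tsv"
    write_kg(benchmark.kg, kg_path)
    paths["kg"] = kg_path

    def write_sigs(sigs: dict[str, Signature], context: str, manifest_name: str) -> Path:
        sig_dir = outdir / f"{context}_signatures"
        sig_dir.mkdir(exist_ok=True)
        manifest = outdir / manifest_name
        with open(manifest, "w", encoding="utf-8") as mfh:
            mfh.write("context_id\tpath\tcontext\n")
            for cid in sorted(sigs):
                fname = cid.replace(":", "_") + ".tsv"
                with open(sig_dir / fname, "w", encoding="utf-8") as fh:
                    fh.write("gene_id\tbinary\n")
                    for g in sorted(sigs[cid].values):
                        fh.write(f"{g}\t{sigs[cid].values[g]}\n")
                mfh.write(f"{cid}\t{sig_dir.name}/{fname}\t{context}\n")
        return manifest

    paths["drug_manifest"] = write_sigs(benchmark.drug_signatures, "drug", "drug_manifest.tsv")
    paths["disease_manifest"] = write_sigs(
        benchmark.disease_signatures, "disease", "disease_manifest.tsv"
    )
    labels_path = outdir / "labels.tsv"
    with open(labels_path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tdisease_id\n")
        for a, b in sorted(benchmark.labels.positives):
            fh.write(f"{a}\t{b}\n")
    paths["labels"] = labels_path
    truth_path = outdir / "truth.json"
    with open(truth_path, "w", encoding="utf-8") as fh:
        json.dump(benchmark.truth.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["truth"] = truth_path
    return paths


def worked_fixture() -> tuple[CausalKG, Signature, Signature]:
    """The five-node documentation fixture and its matching signatures.

    KG: D -inhibits-> P1, P1 -activates-> P2, P2 -inhibits-> P3,
    P3 -activates-> X, plus the shortcut D -activates-> P2.  Exactly two
    acyclic paths run from D to X; the shorter one (D→P2→P3→X) has an
    inhibitory cumulative effect on X and the fixture signatures are built to
    make it survive both checks, so reasoning prioritizes (D, X) under the
    default configuration.
    """
    kg = CausalKG()
    kg.add_node("D", NodeKind.CHEMICAL)
    for p in ("P1", "P2", "P3"):
        kg.add_node(p, NodeKind.PROTEIN)
    kg.add_node("X", NodeKind.DISEASE)
    kg.add_edge("D", "P1", -1)
    kg.add_edge("P1", "P2", 1)
    kg.add_edge("P2", "P3", -1)
    kg.add_edge("P3", "X", 1)
    kg.add_edge("D", "P2", 1)
    drug_sig = Signature(
        {"P1": -1, "P2": 1, "P3": -1}, SignatureContext.DRUG, "D"
    )
    disease_sig = Signature(
        {"P1": 1, "P2": -1, "P3": 1}, SignatureContext.DISEASE, "X"
    )
    return kg, drug_sig, disease_sig
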