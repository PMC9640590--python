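"""Synthetic benchmark collections with planted regulatory structure.

The generator emulates the statistical structure the regulome method
assumes: transcription factors coordinately drive the expression of the
genes they bind.  Each TF gets a *program* — a gene subset it binds at an
elevated rate ``p_driver`` against a background binding rate ``p_bg``.
An entity (drug or disease) is characterised by a few driver TFs with
directions; genes bound by a driver receive expression scores centred at
``±mu`` while all other genes are pure noise.

Planted therapeutic drugs share their disease's driver TFs, with equal
directions for positive-polarity diseases (immune-like) and opposite
directions for negative-polarity diseases (cancer-like), so the
drug-disease regulome correlation is planted by construction.  A
``gene``-level mode instead plants expression programs on random gene
sets not mediated by any TF — therapeutic drugs exactly reverse the
disease program — which is the regime where transcriptome matching
should win and regulome matching should not.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .binding import BindingTable
from .errors import InvalidParameterError
from .scoring import ApprovedDrugMap
from .signatures import TranscriptomeSignature

__all__ = [
    "SimulationConfig", "GroundTruth", "SyntheticCollection",
    "simulate_binding", "simulate_entity_signature", "simulate_collection",
    "write_collection", "read_ground_truth",
]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic collection.

    Defaults define the reference benchmark: 1,000 genes, 50 TFs,
    200 drugs, 50 diseases, background binding 0.1, driver binding 0.8,
    planted effect size mu = 3.0 against unit noise.
    """

    n_genes: int = 1000
    n_tfs: int = 50
    n_drugs: int = 200
    n_diseases: int = 50
    p_bg: float = 0.1
    p_driver: float = 0.8
    drivers_per_program: int = 2
    program_fraction: float = 0.1   # genes per TF program, as a fraction of n_genes
    therapeutic_fraction: float = 0.25
    mu: float = 3.0
    noise_sd: float = 1.0
    polarity_by_disease: dict = field(default_factory=dict)
    effect_level: str = "tf"        # "tf" | "gene"
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_tfs", "n_drugs", "n_diseases", "drivers_per_program"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be >= 1")
        if not (0.0 < self.p_bg < 1.0):
            raise InvalidParameterError("p_bg must be in (0, 1)")
        if not (self.p_bg < self.p_driver <= 1.0):
            raise InvalidParameterError("p_driver must be in (p_bg, 1]")
        if not (0.0 < self.therapeutic_fraction < 1.0):
            raise InvalidParameterError("therapeutic_fraction must be in (0, 1)")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be nonnegative")
        if self.drivers_per_program > self.n_tfs:
            raise InvalidParameterError("drivers_per_program exceeds n_tfs")
        if self.effect_level not in ("tf", "gene"):
            raise InvalidParameterError("effect_level must be 'tf' or 'gene'")
        if self.n_therapeutic < self.n_diseases:
            raise InvalidParameterError(
                f"therapeutic_fraction {self.therapeutic_fraction} yields "
                f"{self.n_therapeutic} therapeutic drugs for {self.n_diseases} diseases; "
                f"need at least one per disease")

    @property
    def n_therapeutic(self) -> int:
        return math.floor(self.therapeutic_fraction * self.n_drugs)

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]

    @property
    def tf_ids(self) -> list[str]:
        return [f"TF{i:03d}" for i in range(self.n_tfs)]

    @property
    def drug_ids(self) -> list[str]:
        return [f"drug{i:03d}" for i in range(self.n_drugs)]

    @property
    def disease_ids(self) -> list[str]:
        return [f"dis{i:02d}" for i in range(self.n_diseases)]

    def default_polarities(self) -> dict[str, str]:
        """Planted polarity per disease: first half negative (cancer-like),
        second half positive (immune-like), unless overridden."""
        out = {}
        for i, dis in enumerate(self.disease_ids):
            out[dis] = self.polarity_by_disease.get(
                dis, "negative" if i < self.n_diseases // 2 else "positive")
        return out


@dataclass
class GroundTruth:
    """What was planted: drivers, therapeutic pairs, polarities."""

    drivers: dict          # entity_id -> {tf_id: +1 | -1}
    gene_programs: dict    # entity_id -> {gene_id: +1 | -1} (gene-level mode)
    therapeutic_pairs: list  # [(disease_id, drug_id), ...]
    polarity: dict         # disease_id -> "positive" | "negative"

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["therapeutic_pairs"] = [list(p) for p in self.therapeutic_pairs]
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            drivers={e: {t: int(d) for t, d in m.items()}
                     for e, m in payload["drivers"].items()},
            gene_programs={e: {g: int(d) for g, d in m.items()}
                           for e, m in payload["gene_programs"].items()},
            therapeutic_pairs=[tuple(p) for p in payload["therapeutic_pairs"]],
            polarity=dict(payload["polarity"]),
        )


@dataclass
class SyntheticCollection:
    config: SimulationConfig
    binding: BindingTable
    drug_signatures: list
    disease_signatures: list
    approved: ApprovedDrugMap
    truth: GroundTruth


def simulate_binding(cfg: SimulationConfig,
                     programs: Mapping[str, set] | None = None,
                     rng: np.random.Generator | None = None) -> BindingTable:
    """Sample a binary binding table.

    Every TF-gene edge is Bernoulli(``p_bg``), except edges from a TF to
    its program genes, which are Bernoulli(``p_driver``).  With no
    programs the table is pure background.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    genes = cfg.gene_ids
    gene_index = {g: j for j, g in enumerate(genes)}
    prob = np.full((cfg.n_tfs, cfg.n_genes), cfg.p_bg)
    for i, tf in enumerate(cfg.tf_ids):
        for g in (programs or {}).get(tf, ()):  # elevated edges
            prob[i, gene_index[g]] = cfg.p_driver
    matrix = rng.random((cfg.n_tfs, cfg.n_genes)) < prob
    return BindingTable(cfg.tf_ids, genes, matrix)


def simulate_entity_signature(cfg: SimulationConfig, binding: BindingTable,
                              drivers: Mapping[str, int],
                              entity_id: str, role: str,
                              rng: np.random.Generator | None = None,
                              gene_program: Mapping[str, int] | None = None
                              ) -> TranscriptomeSignature:
    """Expression scores with planted driver effects.

    A gene bound by driver TF ``t`` (direction ``d``) gets mean
    ``d * mu``; effects of multiple drivers add.  In gene-level mode
    (``gene_program``) the means attach directly to the listed genes,
    bypassing binding.  Gaussian noise with sd ``noise_sd`` is added
    everywhere; ``noise_sd = 0`` gives the exact planted means.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    means = np.zeros(cfg.n_genes)
    gene_index = {g: j for j, g in enumerate(binding.gene_ids)}
    if gene_program:
        for g, d in gene_program.items():
            means[gene_index[g]] += d * cfg.mu
    else:
        tf_index = {t: i for i, t in enumerate(binding.tf_ids)}
        for tf, direction in drivers.items():
            means += direction * cfg.mu * binding.matrix[tf_index[tf]]
    scores = means + rng.normal(0.0, cfg.noise_sd, cfg.n_genes) if cfg.noise_sd > 0 else means
    return TranscriptomeSignature(entity_id=entity_id, role=role,
                                  genes=np.asarray(binding.gene_ids, dtype=object),
                                  scores=scores)


def _sample_drivers(cfg: SimulationConfig, rng: np.random.Generator) -> dict[str, int]:
    tfs = rng.choice(cfg.n_tfs, size=cfg.drivers_per_program, replace=False)
    dirs = rng.choice([-1, 1], size=cfg.drivers_per_program)
    return {cfg.tf_ids[int(t)]: int(d) for t, d in zip(tfs, dirs)}


def _sample_gene_program(cfg: SimulationConfig, rng: np.random.Generator,
                         size: int) -> dict[str, int]:
    genes = rng.choice(cfg.n_genes, size=size, replace=False)
    dirs = rng.choice([-1, 1], size=size)
    return {cfg.gene_ids[int(g)]: int(d) for g, d in zip(genes, dirs)}


def simulate_collection(cfg: SimulationConfig) -> SyntheticCollection:
    """Generate the full benchmark: binding, signatures, approved map, truth.

    Deterministic for a fixed config (all randomness flows from
    ``cfg.seed`` through one generator in a fixed consumption order).
    """
    rng = np.random.default_rng(cfg.seed)
    polarity = cfg.default_polarities()
    program_size = max(1, math.floor(cfg.program_fraction * cfg.n_genes))

    drivers: dict[str, dict[str, int]] = {}
    gene_programs: dict[str, dict[str, int]] = {}
    therapeutic_pairs: list[tuple[str, str]] = []
    n_therapeutic = cfg.n_therapeutic

    if cfg.effect_level == "tf":
        # Every TF owns a program gene set; binding is elevated there.
        tf_programs = {tf: set(_sample_gene_program(cfg, rng, program_size))
                       for tf in cfg.tf_ids}
        binding = simulate_binding(cfg, programs=tf_programs, rng=rng)
        for dis in cfg.disease_ids:
            drivers[dis] = _sample_drivers(cfg, rng)
        for j, drug in enumerate(cfg.drug_ids):
            if j < n_therapeutic:
                dis = cfg.disease_ids[j % cfg.n_diseases]
                flip = 1 if polarity[dis] == "positive" else -1
                drivers[drug] = {t: d * flip for t, d in drivers[dis].items()}
                therapeutic_pairs.append((dis, drug))
            else:
                drivers[drug] = _sample_drivers(cfg, rng)
    else:
        # Gene-level effects: programs attach to genes directly; binding
        # is pure background, so no TF mediates the planted signal.
        binding = simulate_binding(cfg, programs=None, rng=rng)
        program_genes = program_size * cfg.drivers_per_program
        for dis in cfg.disease_ids:
            gene_programs[dis] = _sample_gene_program(cfg, rng, program_genes)
        for j, drug in enumerate(cfg.drug_ids):
            if j < n_therapeutic:
                dis = cfg.disease_ids[j % cfg.n_diseases]
                gene_programs[drug] = {g: -d for g, d in gene_programs[dis].items()}
                therapeutic_pairs.append((dis, drug))
            else:
                gene_programs[drug] = _sample_gene_program(cfg, rng, program_genes)

    def make_sig(entity_id: str, role: str) -> TranscriptomeSignature:
        return simulate_entity_signature(
            cfg, binding, drivers.get(entity_id, {}), entity_id, role, rng=rng,
            gene_program=gene_programs.get(entity_id))

    disease_sigs = [make_sig(d, "disease") for d in cfg.disease_ids]
    drug_sigs = [make_sig(d, "drug") for d in cfg.drug_ids]
    approved = ApprovedDrugMap.from_pairs(therapeutic_pairs)
    truth = GroundTruth(drivers=drivers, gene_programs=gene_programs,
                        therapeutic_pairs=therapeutic_pairs, polarity=polarity)
    return SyntheticCollection(cfg, binding, drug_sigs, disease_sigs, approved, truth)


def write_collection(coll: SyntheticCollection, out_dir) -> dict[str, Path]:
    """Emit the collection as TSVs plus ground_truth.json; returns the paths."""
    from .binding import write_binding_table
    from .signatures import write_signature_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "binding": out / "binding.tsv",
        "signatures": out / "signatures.tsv",
        "metadata": out / "signature_metadata.tsv",
        "approved": out / "approved.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_binding_table(coll.binding, paths["binding"], fmt="matrix")
    write_signature_matrix(coll.disease_signatures + coll.drug_signatures,
                           paths["signatures"], paths["metadata"])
    coll.approved.write_tsv(paths["approved"])
    coll.truth.to_json(paths["ground_truth"])
    return paths


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_json(path)
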