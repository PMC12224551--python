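"""Ground-truthed synthetic datasets for the whole pipeline.

The generator emulates the statistical structure of a multi-genus bacterial
pan-genome study: an open pan-genome per genus (universal core families
plus Bernoulli-sampled shell and cloud families), planted colocated BGCs of
controlled per-genus prevalence, and sequence divergence applied on a
two-level star phylogeny (a phylum root, genus ancestors, then genomes).
Outputs are emitted in exactly the formats the pipeline consumes — genome
metadata TSV, Roary-style presence/absence CSV, and one region GenBank file
per planted or decoy cluster occurrence — together with a machine-readable
ground truth for precision/recall evaluation.

Planted-cluster prevalence is realized exactly (round(prevalence x
n_genomes) carrier genomes drawn without replacement), so the set of
clusters that must be called conserved is derivable from the parameters
alone.  Shell and cloud presence stays Bernoulli per genome, which is what
makes the pan-genome "open".

Horizontally transferred clusters draw their ancestral sequences from an
independent out-group root and skip genus-level divergence, so copies of an
HGT cluster resemble each other across genera more than vertically
inherited genes do — mimicking a recently transferred cluster without any
phylogenetic machinery.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .bgc_conservation import GenusConservationCall, PhylumGroup
from .formats import (
    BgcRegion,
    CdsFeature,
    GenomeMetadata,
    PresenceAbsenceMatrix,
    write_metadata_tsv,
    write_region_genbank,
    write_roary_csv,
)

__all__ = [
    "ClusterSpec",
    "SimParams",
    "SimTruth",
    "SimDataset",
    "default_cluster_specs",
    "simulate_dataset",
    "mutate_sequence",
    "truth_eval",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NT_ALPHABET = "ACGT"

# one fixed codon per amino acid for deterministic back-translation
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

_PRODUCT_CLASSES = ["terpene", "NRPS", "T1PKS", "T3PKS", "RiPP-like", "other"]


@dataclass(frozen=True)
class ClusterSpec:
    """One planted cluster: gene count, genus range, per-genus prevalence."""

    label: str
    n_genes: int
    prevalence_per_genus: Mapping[str, float]
    colocated: bool = True
    hgt: bool = False

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("a cluster needs at least 2 genes")
        for genus, p in self.prevalence_per_genus.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence for {genus} out of [0,1]: {p}")

    @property
    def genera_present(self) -> set[str]:
        return {g for g, p in self.prevalence_per_genus.items() if p > 0}

    @property
    def family_ids(self) -> list[str]:
        return [f"{self.label}_gene{j}" for j in range(1, self.n_genes + 1)]


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one synthetic dataset.

    Defaults describe a three-genus, eight-genomes-per-genus design with an
    open pan-genome (200 core, 300 shell, 300 cloud families per genus
    universe), two conserved planted clusters (prevalence 0.75, four genes)
    plus three sub-threshold decoys (prevalence 0.25), and 2% within-genus
    sequence divergence.
    """

    seed: int = 0
    n_genera: int = 3
    genomes_per_genus: int = 8
    n_core: int = 200
    n_shell: int = 300
    n_cloud: int = 300
    shell_presence_prob: float = 0.5
    cloud_presence_prob: float = 0.1
    planted_clusters: tuple[ClusterSpec, ...] | None = None
    divergence_within_genus: float = 0.02
    divergence_between_genera: float = 0.10
    protein_length_range: tuple[int, int] = (60, 120)

    def __post_init__(self) -> None:
        for name in ("shell_presence_prob", "cloud_presence_prob",
                     "divergence_within_genus", "divergence_between_genera"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} out of [0,1]: {v}")
        for name in ("n_genera", "genomes_per_genus"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("n_core", "n_shell", "n_cloud"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def genera(self) -> list[str]:
        return [f"Genus{chr(ord('A') + i)}" for i in range(self.n_genera)]

    def resolved_clusters(self) -> list[ClusterSpec]:
        if self.planted_clusters is not None:
            specs = list(self.planted_clusters)
        else:
            specs = default_cluster_specs(self.genera)
        genera = set(self.genera)
        for spec in specs:
            unknown = set(spec.prevalence_per_genus) - genera
            if unknown:
                raise ValueError(f"cluster {spec.label}: unknown genera {sorted(unknown)}")
        return specs


def default_cluster_specs(
    genera: Sequence[str],
    n_conserved: int = 2,
    n_decoy: int = 3,
    conserved_prevalence: float = 0.75,
    decoy_prevalence: float = 0.25,
    n_genes: int = 4,
) -> list[ClusterSpec]:
    """Two phylum-wide conserved clusters plus three sub-threshold decoys."""
    specs = []
    for k in range(1, n_conserved + 1):
        specs.append(
            ClusterSpec(
                label=f"bgc{k}",
                n_genes=n_genes,
                prevalence_per_genus={g: conserved_prevalence for g in genera},
            )
        )
    for k in range(1, n_decoy + 1):
        specs.append(
            ClusterSpec(
                label=f"decoy{k}",
                n_genes=n_genes,
                prevalence_per_genus={g: decoy_prevalence for g in genera},
            )
        )
    return specs


@dataclass
class SimTruth:
    """Planted ground truth, derivable from the parameters alone."""

    family_bin: dict[str, str]  # family_id -> core|shell|cloud|cluster
    planted: dict[str, dict]  # label -> {genera, genomes per genus, families}
    expected_conserved: dict[str, set[str]]  # genus -> cluster labels

    def expected_phylum(self, min_genera: int = 7) -> set[str]:
        """Labels whose genus-conserved count reaches ``min_genera``."""
        counts: dict[str, int] = {}
        for labels in self.expected_conserved.values():
            for lab in labels:
                counts[lab] = counts.get(lab, 0) + 1
        return {lab for lab, n in counts.items() if n >= min_genera}

    def to_json(self) -> str:
        payload = {
            "family_bin": self.family_bin,
            "planted": {
                lab: {
                    "genera": sorted(info["genera"]),
                    "genomes": {g: sorted(v) for g, v in info["genomes"].items()},
                    "families": sorted(info["families"]),
                }
                for lab, info in self.planted.items()
            },
            "expected_conserved": {
                g: sorted(v) for g, v in self.expected_conserved.items()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class SimDataset:
    """Everything one simulation produced, in memory and (optionally) on disk."""

    params: SimParams
    metadata: list[GenomeMetadata]
    matrix: PresenceAbsenceMatrix
    regions: list[BgcRegion]
    truth: SimTruth
    out_dir: Path | None = None

    @property
    def paths(self) -> dict[str, object]:
        if self.out_dir is None:
            return {}
        return {
            "metadata": self.out_dir / "metadata.tsv",
            "matrix": self.out_dir / "gene_presence_absence.csv",
            "regions": sorted((self.out_dir / "regions").glob("*.gbk")),
            "truth": self.out_dir / "truth.json",
        }


# ---------------------------------------------------------------------------
# Sequence machinery
# ---------------------------------------------------------------------------


def mutate_sequence(seq: str, d: float, rng: np.random.Generator, alphabet: str | None = None) -> str:
    """Substitute each site independently with probability ``d`` to a
    uniformly chosen *different* symbol; length is preserved."""
    if not 0 <= d <= 1:
        raise ValueError("d must be in [0,1]")
    if not seq:
        return seq
    if alphabet is None:
        alphabet = NT_ALPHABET if set(seq) <= set(NT_ALPHABET) else AA_ALPHABET
    k = len(alphabet)
    if k < 2 and d > 0:
        raise ValueError("cannot substitute on a <2-symbol alphabet")
    index = {c: i for i, c in enumerate(alphabet)}
    arr = np.fromiter((index[c] for c in seq), dtype=np.int64, count=len(seq))
    hits = rng.random(len(seq)) < d
    if hits.any():
        shifts = rng.integers(1, k, size=int(hits.sum()))
        arr[hits] = (arr[hits] + shifts) % k
    return "".join(alphabet[i] for i in arr)


def _random_protein(rng: np.random.Generator, length_range: tuple[int, int]) -> str:
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    # keep an invariant leading methionine so translations look gene-like
    body = rng.integers(0, len(AA_ALPHABET), size=length - 1)
    return "M" + "".join(AA_ALPHABET[i] for i in body)


def back_translate(protein: str) -> str:
    return "".join(_CODON[a] for a in protein)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def simulate_dataset(params: SimParams, out_dir: str | Path | None = None) -> SimDataset:
    """Generate one complete synthetic dataset (and optionally write it out).

    Same parameters (including the seed) produce byte-identical files.
    """
    rng = np.random.default_rng(params.seed)
    hgt_rng = np.random.default_rng(params.seed + 10_007)  # independent out-group root
    genera = params.genera
    clusters = params.resolved_clusters()

    # -- family universe and root sequences ---------------------------------
    family_bin: dict[str, str] = {}
    families: list[str] = []
    for i in range(1, params.n_core + 1):
        fam = f"core{i:05d}"
        families.append(fam)
        family_bin[fam] = "core"
    for i in range(1, params.n_shell + 1):
        fam = f"shell{i:05d}"
        families.append(fam)
        family_bin[fam] = "shell"
    for i in range(1, params.n_cloud + 1):
        fam = f"cloud{i:05d}"
        families.append(fam)
        family_bin[fam] = "cloud"
    cluster_fams: list[str] = []
    for spec in clusters:
        for fam in spec.family_ids:
            families.append(fam)
            cluster_fams.append(fam)
            family_bin[fam] = "cluster"

    root_protein: dict[str, str] = {}
    for fam in families:
        src = hgt_rng if any(
            spec.hgt and fam in spec.family_ids for spec in clusters
        ) else rng
        root_protein[fam] = _random_protein(src, params.protein_length_range)

    hgt_fams = {fam for spec in clusters if spec.hgt for fam in spec.family_ids}

    # genus-level ancestors (HGT clusters skip genus divergence: their copies
    # stem from one recent out-group donor, not the vertical root)
    genus_protein: dict[tuple[str, str], str] = {}
    for genus in genera:
        for fam in families:
            d = 0.0 if fam in hgt_fams else params.divergence_between_genera
            genus_protein[(genus, fam)] = mutate_sequence(
                root_protein[fam], d, rng, AA_ALPHABET
            )

    # -- genome composition -------------------------------------------------
    metadata: list[GenomeMetadata] = []
    genome_ids: list[str] = []
    genomes_by_genus: dict[str, list[str]] = {}
    for genus in genera:
        ids = [f"{genus}_g{j}" for j in range(1, params.genomes_per_genus + 1)]
        genomes_by_genus[genus] = ids
        genome_ids.extend(ids)
        metadata.extend(GenomeMetadata(genome_id=g, genus=genus) for g in ids)

    # planted cluster carriers: exact counts, sampled without replacement
    carriers: dict[tuple[str, str], list[str]] = {}
    for spec in clusters:
        for genus in genera:
            p = spec.prevalence_per_genus.get(genus, 0.0)
            n_carry = int(round(p * params.genomes_per_genus))
            if p > 0 and not genomes_by_genus[genus]:
                raise ValueError(
                    f"cluster {spec.label}: prevalence > 0 for empty genus {genus}"
                )
            chosen = sorted(
                rng.choice(genomes_by_genus[genus], size=n_carry, replace=False)
            ) if n_carry else []
            carriers[(spec.label, genus)] = list(chosen)

    present: dict[str, list[str]] = {}  # genome -> family list, genomic order
    for genus in genera:
        for gid in genomes_by_genus[genus]:
            fams = [f"core{i:05d}" for i in range(1, params.n_core + 1)]
            shell_mask = rng.random(params.n_shell) < params.shell_presence_prob
            fams += [
                f"shell{i + 1:05d}" for i in range(params.n_shell) if shell_mask[i]
            ]
            cloud_mask = rng.random(params.n_cloud) < params.cloud_presence_prob
            fams += [
                f"cloud{i + 1:05d}" for i in range(params.n_cloud) if cloud_mask[i]
            ]
            for spec in clusters:
                if gid in carriers[(spec.label, genus)]:
                    fams += spec.family_ids
            present[gid] = fams

    # -- locus tags and matrix ---------------------------------------------
    cells: dict[tuple[str, str], list[str]] = {}
    tag_of: dict[tuple[str, str], str] = {}
    for gid in genome_ids:
        for ordinal, fam in enumerate(present[gid], start=1):
            tag = f"{gid}_{ordinal:05d}"
            tag_of[(gid, fam)] = tag
            cells[(fam, gid)] = [tag]
    matrix_families = [f for f in families if any((f, g) in cells for g in genome_ids)]
    matrix = PresenceAbsenceMatrix(matrix_families, list(genome_ids), cells)

    # -- region files for planted clusters ----------------------------------
    regions: list[BgcRegion] = []
    genus_of = {m.genome_id: m.genus for m in metadata}
    for spec_idx, spec in enumerate(clusters):
        product = _PRODUCT_CLASSES[spec_idx % len(_PRODUCT_CLASSES)]
        for genus in genera:
            for gid in carriers[(spec.label, genus)]:
                regions.append(
                    _emit_region(spec, gid, genus_of[gid], product, genus_protein,
                                 tag_of, params, rng)
                )
    regions.sort(key=lambda r: r.region_id)

    # -- ground truth --------------------------------------------------------
    planted = {}
    expected: dict[str, set[str]] = {g: set() for g in genera}
    for spec in clusters:
        genomes = {
            genus: carriers[(spec.label, genus)]
            for genus in genera
            if carriers[(spec.label, genus)]
        }
        planted[spec.label] = {
            "genera": set(genomes),
            "genomes": genomes,
            "families": set(spec.family_ids),
        }
        for genus in genera:
            n_carry = len(carriers[(spec.label, genus)])
            frac = n_carry / params.genomes_per_genus
            # the conservation rule the pipeline must reproduce
            if frac >= 0.5 and spec.n_genes >= 2:
                expected[genus].add(spec.label)
    truth = SimTruth(family_bin=family_bin, planted=planted, expected_conserved=expected)

    dataset = SimDataset(
        params=params, metadata=metadata, matrix=matrix, regions=regions, truth=truth
    )
    if out_dir is not None:
        _write_dataset(dataset, Path(out_dir))
    return dataset


def _emit_region(
    spec: ClusterSpec,
    genome_id: str,
    genus: str,
    product: str,
    genus_protein: Mapping[tuple[str, str], str],
    tag_of: Mapping[tuple[str, str], str],
    params: SimParams,
    rng: np.random.Generator,
) -> BgcRegion:
    """Lay one cluster occurrence onto its own contig as a colocated CDS run."""
    contig = f"{genome_id}_ctg_{spec.label}"
    spacer_len = 80
    pos = 1
    seq_parts: list[str] = []
    cds_list: list[CdsFeature] = []
    for fam in spec.family_ids:
        spacer = "".join(
            NT_ALPHABET[i] for i in rng.integers(0, 4, size=spacer_len)
        )
        seq_parts.append(spacer)
        pos += spacer_len
        protein = mutate_sequence(
            genus_protein[(genus, fam)], params.divergence_within_genus, rng, AA_ALPHABET
        )
        nt = back_translate(protein)
        seq_parts.append(nt)
        cds_list.append(
            CdsFeature(
                locus_tag=tag_of[(genome_id, fam)],
                contig_id=contig,
                start=pos,
                end=pos + len(nt) - 1,
                strand="+",
                product=fam,
                translation=protein,
                nt_seq=nt,
            )
        )
        pos += len(nt)
    tail = "".join(NT_ALPHABET[i] for i in rng.integers(0, 4, size=spacer_len))
    seq_parts.append(tail)
    full_seq = "".join(seq_parts)
    return BgcRegion(
        region_id=f"{genome_id}|{contig}|1-{len(full_seq)}",
        genome_id=genome_id,
        contig_id=contig,
        start=1,
        end=len(full_seq),
        product_classes=[product],
        cds=cds_list,
        nt_seq=full_seq,
    )


def _write_dataset(dataset: SimDataset, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "regions").mkdir(exist_ok=True)
    write_metadata_tsv(dataset.metadata, out_dir / "metadata.tsv")
    write_roary_csv(dataset.matrix, out_dir / "gene_presence_absence.csv")
    for region in dataset.regions:
        fname = region.region_id.replace("|", "__").replace("/", "_") + ".gbk"
        write_region_genbank(region, out_dir / "regions" / fname)
    (out_dir / "truth.json").write_text(dataset.truth.to_json())
    (out_dir / "params.json").write_text(
        json.dumps(
            dataclasses.asdict(dataset.params), indent=2, sort_keys=True, default=list
        )
    )
    dataset.out_dir = out_dir


# ---------------------------------------------------------------------------
# Truth evaluation
# ---------------------------------------------------------------------------


def _label_of_family(defining: set[str], truth: SimTruth) -> str | None:
    """Planted cluster label with the largest family overlap, if any."""
    best_label, best_n = None, 0
    for label in sorted(truth.planted):
        n = len(defining & truth.planted[label]["families"])
        if n > best_n:
            best_label, best_n = label, n
    return best_label


def truth_eval(
    genus_calls: Mapping[str, Sequence[GenusConservationCall]],
    truth: SimTruth,
    phylum_calls: Sequence[tuple[PhylumGroup, bool]] | None = None,
    min_genera: int = 7,
) -> dict[str, tuple[float, float]]:
    """Precision/recall of conservation calls against the planted truth.

    ``genus_calls`` maps genus -> conservation calls for that genus.  A call
    flagged conserved is matched to the planted cluster sharing most of its
    defining families; calls matching nothing count as false positives.
    When ``phylum_calls`` is given, phylum-level precision/recall is
    evaluated against the labels expected to reach ``min_genera`` genera.
    """
    unknown = set(genus_calls) - set(truth.expected_conserved)
    if unknown:
        raise ValueError(f"calls for genera absent from truth: {sorted(unknown)}")

    predicted: set[tuple[str, str]] = set()
    false_pos = 0
    for genus, calls in genus_calls.items():
        for call in calls:
            if not call.is_conserved:
                continue
            label = _label_of_family(call.bgc_family.defining_families, truth)
            if label is None:
                false_pos += 1
            else:
                predicted.add((genus, label))
    expected = {
        (genus, label)
        for genus, labels in truth.expected_conserved.items()
        for label in labels
    }
    tp = len(predicted & expected)
    fp = false_pos + len(predicted - expected)
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / len(expected) if expected else 1.0
    out = {"genus": (precision, recall)}

    if phylum_calls is not None:
        pred_labels: set[str] = set()
        fp_ph = 0
        for group, flag in phylum_calls:
            if not flag:
                continue
            defining = set().union(
                *(fam.defining_families for _, fam in group.members)
            ) if group.members else set()
            label = _label_of_family(defining, truth)
            if label is None:
                fp_ph += 1
            else:
                pred_labels.add(label)
        exp_labels = truth.expected_phylum(min_genera)
        tp_ph = len(pred_labels & exp_labels)
        fp_ph += len(pred_labels - exp_labels)
        precision_ph = tp_ph / (tp_ph + fp_ph) if (tp_ph + fp_ph) else 1.0
        recall_ph = tp_ph / len(exp_labels) if exp_labels else 1.0
        out["phylum"] = (precision_ph, recall_ph)
    return out
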