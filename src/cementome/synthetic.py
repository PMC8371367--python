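"""Seeded synthetic proteome pairs, annotations and contigs with planted truth.

The generator emulates the statistical structure of a two-species adhesive
proteome comparison at desk scale: shared bulk-protein families mutated
from common ancestors to a controlled cross-species identity,
composition-biased protein classes (Gly/Ala/Ser/Thr-rich, Leu-rich,
Cys-rich), signal peptides, ER-retained (HDEL-tagged) proteins,
intracellular contaminants, domain-tagged pheromones / enzymes /
homologous proteins, and genomic contigs carrying a split coding sequence.
Every protein carries ground-truth labels, so each pipeline stage can be
tested for exact recovery without any external download.

All randomness flows from a single integer seed; identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from cementome.seqio import AMINO_ACIDS, AnnotationRow, SequenceRecord, write_annotations, write_fasta

#: average protein residue frequencies (Robinson & Robinson-style background);
#: using a realistic background keeps the alignment score statistics in the
#: regime the default Karlin-Altschul parameters describe
BACKGROUND_FREQS: dict[str, float] = {
    "A": 0.078, "C": 0.019, "D": 0.054, "E": 0.063, "F": 0.039,
    "G": 0.074, "H": 0.022, "I": 0.051, "K": 0.057, "L": 0.090,
    "M": 0.022, "N": 0.045, "P": 0.052, "Q": 0.043, "R": 0.051,
    "S": 0.071, "T": 0.058, "V": 0.064, "W": 0.013, "Y": 0.032,
}

#: class-conditioned residue frequency boosts (residue -> target frequency);
#: non-focal residues keep the background distribution, rescaled
CLASS_BIAS: dict[str, dict[str, float]] = {
    "GrCP": {"G": 0.20, "A": 0.15, "S": 0.14, "T": 0.09},
    "LrCP": {"L": 0.22, "Y": 0.08, "I": 0.08, "R": 0.08},
    "CrCP": {"C": 0.16, "K": 0.10},
    "uniform": {},
}

_HYDROPHOBIC = "AILMFVW"
#: signal-peptide core composition: mostly Leu/Ala/Val, Trp rare, as in real
#: secretion signals (keeps unrelated signal peptides from spuriously aligning)
_HYDROPHOBIC_FREQS = (0.22, 0.12, 0.34, 0.06, 0.10, 0.14, 0.02)

_CODONS = {  # one arbitrary codon table is enough for back-translation sampling
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"], "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"], "F": ["TTT", "TTC"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"], "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"], "W": ["TGG"], "Y": ["TAT", "TAC"],
    "X": ["NNN"],
}


@dataclass
class SyntheticConfig:
    """Generator configuration; the seed fully determines the output.

    Defaults describe a scaled-down two-proteome study: eight shared bulk
    families of three members per species at ~40% cross-species identity
    (the typical range observed between distantly related barnacles), a
    handful of species-unique bulk proteins (a subset with genome-level
    matches in the other species), composition classes dominated by
    Gly/Ala/Ser/Thr- and Leu-rich proteins with a minority Cys-rich class,
    intracellular contaminants, one ER-retained protein per species, and
    shared domain-tagged pheromones, enzymes and homologous proteins.
    """

    seed: int = 0
    n_shared_families: int = 8
    family_size_A: int = 3
    family_size_B: int = 3
    target_identity: float = 0.4
    within_identity: float = 0.75
    n_unique_A: int = 6
    n_unique_B: int = 5
    n_unique_genome_matched_A: int = 2
    n_unique_genome_matched_B: int = 2
    class_mix: dict = field(
        default_factory=lambda: {"GrCP": 0.45, "LrCP": 0.35, "CrCP": 0.10, "uniform": 0.10}
    )
    n_contaminants: int = 3
    n_er_proteins: int = 1
    n_pheromone_a2m: int = 2
    n_pheromone_wsp: int = 2
    n_enzyme: int = 3
    n_homologous: int = 2
    signal_peptide_rate: float = 0.7
    length_range: tuple[int, int] = (150, 400)
    contig_gap_nt: int = 120

    def __post_init__(self) -> None:
        if not (0.0 < self.target_identity <= 1.0):
            raise ValueError("target_identity must be in (0, 1]")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        if self.n_shared_families > 0 and (self.family_size_A < 1 or self.family_size_B < 1):
            raise ValueError("family sizes must be >= 1 when shared families are requested")
        if self.n_unique_genome_matched_A > self.n_unique_A or self.n_unique_genome_matched_B > self.n_unique_B:
            raise ValueError("genome-matched unique counts cannot exceed unique counts")


@dataclass
class TruthLabels:
    """Ground truth per protein and per contig, keyed by accession."""

    proteins: dict[str, dict] = field(default_factory=dict)
    contigs: dict[str, dict] = field(default_factory=dict)

    def of_category(self, species: str, category: str) -> set[str]:
        return {
            acc for acc, t in self.proteins.items()
            if t["species"] == species and t["category"] == category
        }

    def homologue_pairs(self) -> list[tuple[str, str]]:
        return [
            (t["partner"], acc) for acc, t in self.proteins.items()
            if t["species"] == "B" and t.get("partner")
        ]


@dataclass
class SyntheticProteomes:
    """In-memory bundle emitted by :func:`generate_proteome_pair`."""

    config: SyntheticConfig
    records_a: list[SequenceRecord]
    records_b: list[SequenceRecord]
    annotations_a: dict[str, AnnotationRow]
    annotations_b: dict[str, AnnotationRow]
    truth: TruthLabels

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.records_a, outdir / "proteome_A.fasta")
        write_fasta(self.records_b, outdir / "proteome_B.fasta")
        write_annotations(self.annotations_a.values(), outdir / "annotations_A.tsv")
        write_annotations(self.annotations_b.values(), outdir / "annotations_B.tsv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump({"proteins": self.truth.proteins, "contigs": self.truth.contigs},
                      fh, indent=1, sort_keys=True)
        with open(outdir / "config.json", "w") as fh:
            cfg = asdict(self.config)
            cfg["length_range"] = list(cfg["length_range"])
            json.dump(cfg, fh, indent=1, sort_keys=True)


def _class_freqs(comp_class: str) -> np.ndarray:
    bias = CLASS_BIAS[comp_class]
    boosted = sum(bias.values())
    rest_total = sum(BACKGROUND_FREQS[aa] for aa in AMINO_ACIDS if aa not in bias)
    scale = (1.0 - boosted) / rest_total
    freqs = np.array(
        [bias.get(aa, BACKGROUND_FREQS[aa] * scale) for aa in AMINO_ACIDS]
    )
    return freqs / freqs.sum()


def _sample_seq(rng: np.random.Generator, length: int, comp_class: str) -> str:
    freqs = _class_freqs(comp_class)
    return "".join(rng.choice(list(AMINO_ACIDS), size=length, p=freqs))


def mutate_sequence(
    seq: str,
    target_identity: float,
    rng: np.random.Generator | int,
    comp_class: str = "uniform",
) -> str:
    """Point-substitute ``seq`` so exactly ``round(t * len)`` positions survive.

    Mutated positions are chosen uniformly without replacement; each
    replacement residue is drawn from the class residue distribution and is
    always different from the original (so the realised identity equals the
    target exactly, up to rounding).  No indels.
    """
    if not (0.0 < target_identity <= 1.0):
        raise ValueError("target_identity must be in (0, 1]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n = len(seq)
    n_keep = int(round(target_identity * n))
    n_mut = n - n_keep
    positions = rng.choice(n, size=n_mut, replace=False)
    freqs = _class_freqs(comp_class)
    chars = list(seq)
    alphabet = list(AMINO_ACIDS)
    for pos in positions:
        new = chars[pos]
        while new == chars[pos]:
            new = rng.choice(alphabet, p=freqs)
        chars[pos] = str(new)
    return "".join(chars)


def _signal_peptide(rng: np.random.Generator) -> str:
    core = "".join(rng.choice(list(_HYDROPHOBIC), size=12, p=_HYDROPHOBIC_FREQS))
    x = rng.choice(list(AMINO_ACIDS))
    return "M" + core + "A" + str(x) + "A"


def generate_proteome_pair(config: SyntheticConfig | None = None) -> SyntheticProteomes:
    """Generate the paired proteomes, annotations and planted truth.

    Shared bulk families: per family an ancestor is drawn from its
    composition class; species-A members derive from the ancestor at the
    within-species identity, species B's first member derives from the
    ancestor at ``target_identity`` (its designated species-A partner is
    the ancestor copy itself, so the pair identity equals the target
    exactly) and further B members derive from that member.  Unique bulk
    proteins, contaminants (intracellular, no signal peptide), ER proteins
    (signal peptide + C-terminal HDEL) and domain-tagged shared pheromones
    / enzymes / homologous proteins are appended per the configured quotas.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    records: dict[str, list[SequenceRecord]] = {"A": [], "B": []}
    annotations: dict[str, dict[str, AnnotationRow]] = {"A": {}, "B": {}}
    truth = TruthLabels()

    classes = list(cfg.class_mix)
    probs = np.array([cfg.class_mix[c] for c in classes], dtype=float)

    def add(species: str, acc: str, seq: str, *, category: str, family: str = "",
            comp_class: str = "", partner: str = "", signal: bool = False,
            intracellular: bool = False, er: bool = False, tags: set[str] | None = None,
            outgroup: bool = False, genome_matched: bool = False) -> None:
        records[species].append(SequenceRecord(id=acc, sequence=seq, alphabet="protein"))
        annotations[species][acc] = AnnotationRow(
            accession=acc, intracellular=intracellular, signal_peptide=signal,
            er_motif=er, domain_tags=set(tags or set()), outgroup_homolog=outgroup,
        )
        truth.proteins[acc] = {
            "species": species, "category": category, "family_id": family,
            "comp_class": comp_class, "partner": partner, "signal_peptide": signal,
            "contaminant": intracellular and not signal, "er_protein": er,
            "genome_matched": genome_matched,
        }

    def maybe_signal(seq: str) -> tuple[str, bool]:
        if rng.random() < cfg.signal_peptide_rate:
            return _signal_peptide(rng) + seq, True
        return seq, False

    # --- shared bulk families -------------------------------------------------
    for f in range(cfg.n_shared_families):
        comp_class = str(rng.choice(classes, p=probs))
        length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        ancestor = _sample_seq(rng, length, comp_class)
        fam = f"FAM{f+1:02d}"
        b_root = mutate_sequence(ancestor, cfg.target_identity, rng, comp_class)
        for i in range(cfg.family_size_A):
            body = ancestor if i == 0 else mutate_sequence(ancestor, cfg.within_identity, rng, comp_class)
            seq, signal = maybe_signal(body)
            add("A", f"AA_{fam}_{i+1}", seq, category="bulk", family=fam,
                comp_class=comp_class, signal=signal)
        for j in range(cfg.family_size_B):
            body = b_root if j == 0 else mutate_sequence(b_root, cfg.within_identity, rng, comp_class)
            seq, signal = maybe_signal(body)
            partner = f"AA_{fam}_1" if j == 0 else ""
            add("B", f"BB_{fam}_{j+1}", seq, category="bulk", family=fam,
                comp_class=comp_class, partner=partner, signal=signal)

    # --- species-unique bulk proteins ----------------------------------------
    for species, n_unique, n_gm in (("A", cfg.n_unique_A, cfg.n_unique_genome_matched_A),
                                    ("B", cfg.n_unique_B, cfg.n_unique_genome_matched_B)):
        for u in range(n_unique):
            comp_class = str(rng.choice(classes, p=probs))
            length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
            seq, signal = maybe_signal(_sample_seq(rng, length, comp_class))
            add(species, f"{species*2}_UNIQ_{u+1}", seq, category="bulk",
                comp_class=comp_class, signal=signal, genome_matched=u < n_gm)

    # --- contaminants and ER-retained proteins -------------------------------
    for species in ("A", "B"):
        for c in range(cfg.n_contaminants):
            length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
            seq = _sample_seq(rng, length, "uniform")
            add(species, f"{species*2}_CONT_{c+1}", seq, category="cellular_excluded",
                comp_class="uniform", intracellular=True)
        for e in range(cfg.n_er_proteins):
            length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
            seq = _signal_peptide(rng) + _sample_seq(rng, length, "uniform") + "HDEL"
            add(species, f"{species*2}_ER_{e+1}", seq, category="cellular_excluded",
                comp_class="uniform", signal=True, er=True)

    # --- shared domain-tagged proteins ---------------------------------------
    tagged_quotas = [
        ("A2M", cfg.n_pheromone_a2m, "pheromone", {"cl08267", "pfam00207", "pfam07677"}, (450, 550)),
        ("WSP", cfg.n_pheromone_wsp, "pheromone", {"cl40423"}, (180, 260)),
        ("ENZ", cfg.n_enzyme, "enzyme_or_inhibitor", None, (250, 400)),
        ("HOM", cfg.n_homologous, "homologous", None, (250, 400)),
    ]
    enzyme_tags = [{"pfam03098"}, {"cd00172"}, {"pfam00095"}]
    homologous_tags = [{"pfam02469"}, {"cd00037"}]
    for prefix, quota, category, fixed_tags, length_range in tagged_quotas:
        for i in range(quota):
            if fixed_tags is not None:
                tags = fixed_tags
            elif category == "enzyme_or_inhibitor":
                tags = enzyme_tags[i % len(enzyme_tags)]
            else:
                tags = homologous_tags[i % len(homologous_tags)]
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            ancestor = _sample_seq(rng, length, "uniform")
            seq_a, signal_a = maybe_signal(ancestor)
            add("A", f"AA_{prefix}_{i+1}", seq_a, category=category, family=prefix,
                comp_class="uniform", signal=signal_a, tags=tags, outgroup=True)
            body_b = mutate_sequence(ancestor, cfg.target_identity, rng, "uniform")
            seq_b, signal_b = maybe_signal(body_b)
            add("B", f"BB_{prefix}_{i+1}", seq_b, category=category, family=prefix,
                comp_class="uniform", partner=f"AA_{prefix}_{i+1}",
                signal=signal_b, tags=tags, outgroup=True)

    return SyntheticProteomes(
        config=cfg,
        records_a=records["A"],
        records_b=records["B"],
        annotations_a=annotations["A"],
        annotations_b=annotations["B"],
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Split-CDS contigs


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Random synonymous back-translation under the standard code."""
    return "".join(str(rng.choice(_CODONS[aa])) for aa in protein)


#: 12-mer containing a stop codon in all three offsets on both strands
#: (TAA forward at offsets 0/1/2 and TTA — the TAA complement — likewise)
_ALL_FRAME_STOPS = "TTAATTAATTAA"


def _ensure_stops(gap: list[str]) -> None:
    """Embed stops so every frame (both strands) crossing the gap is interrupted.

    The first and last gap codons are stops flush against the flanking
    exons (each exon starts/ends on a codon boundary, so these sit in the
    exons' own reading frames and stop any read-through); a 12-nt block
    covering all six frames is embedded in between.  Fully guaranteed for
    gaps of >= 18 nt; shorter gaps get a truncated block, best effort.
    """
    gap[:3] = list("TAA")
    if len(gap) >= 6:
        gap[-3:] = list("TAA")
    block = _ALL_FRAME_STOPS[: max(0, len(gap) - 6)]
    gap[3 : 3 + len(block)] = list(block)


def build_split_cds_contig(
    protein: SequenceRecord,
    gap_nt: int = 120,
    seed: int | np.random.Generator = 0,
    split_fraction: float = 0.33,
    flank_nt: int = 60,
    reverse: bool = False,
) -> tuple[SequenceRecord, list[tuple[int, int]]]:
    """Back-translate ``protein`` into a contig split into two exons.

    The coding sequence is cut at a codon boundary (``split_fraction`` of
    the way along) and the two pieces are separated by ``gap_nt`` random
    nucleotides patched to contain at least one stop codon in every frame
    on both strands; random flanks of ``flank_nt`` are added.  Returns the
    contig and the exon truth spans in forward 1-based coordinates (on the
    forward strand even when ``reverse`` places the gene on the minus
    strand).
    """
    if len(protein) < 60:
        raise ValueError("need a protein of length >= 60 to split meaningfully")
    if gap_nt < 3:
        raise ValueError("gap_nt must be >= 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(int(seed))
    cds = back_translate(protein.sequence, rng)
    cut = 3 * max(1, min(len(protein) - 1, int(round(split_fraction * len(protein)))))
    exon1, exon2 = cds[:cut], cds[cut:]
    gap = list("".join(rng.choice(["A", "C", "G", "T"]) for _ in range(gap_nt)))
    _ensure_stops(gap)
    flank5 = "".join(rng.choice(["A", "C", "G", "T"]) for _ in range(flank_nt))
    flank3 = "".join(rng.choice(["A", "C", "G", "T"]) for _ in range(flank_nt))
    contig_seq = flank5 + exon1 + "".join(gap) + exon2 + flank3
    spans = [
        (flank_nt + 1, flank_nt + len(exon1)),
        (flank_nt + len(exon1) + gap_nt + 1, flank_nt + len(exon1) + gap_nt + len(exon2)),
    ]
    if reverse:
        from Bio.Seq import Seq

        length = len(contig_seq)
        contig_seq = str(Seq(contig_seq).reverse_complement())
        spans = [(length - e + 1, length - s + 1) for s, e in reversed(spans)]
    contig = SequenceRecord(id=f"contig_{protein.id}", sequence=contig_seq, alphabet="dna")
    return contig, spans


# ---------------------------------------------------------------------------
# Distance-tree fixtures (family-signal vs species-signal)


def pheromone_tree_fixture(
    kind: str, seed: int = 0, n_families: int = 2, length: int = 250
) -> tuple[list[SequenceRecord], dict[str, str], dict[str, str]]:
    """Small two-species protein sets with controlled tree signal.

    ``kind="family"`` plants stronger within-family than within-species
    identity (alpha-macroglobulin-pheromone-like: trees group by family);
    ``kind="species"`` plants the opposite (waterborne-settlement-
    pheromone-like: trees group by species).  Returns the records plus
    accession -> family and accession -> species maps.
    """
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    family_of: dict[str, str] = {}
    species_of: dict[str, str] = {}
    if kind == "family":
        for f in range(n_families):
            ancestor = _sample_seq(rng, length, "uniform")
            for sp in ("A", "B"):
                acc = f"{sp}_fam{f+1}"
                records.append(SequenceRecord(id=acc, alphabet="protein",
                                              sequence=mutate_sequence(ancestor, 0.9, rng)))
                family_of[acc] = f"fam{f+1}"
                species_of[acc] = sp
    elif kind == "species":
        root = _sample_seq(rng, length, "uniform")
        for sp in ("A", "B"):
            sp_ancestor = mutate_sequence(root, 0.55, rng)
            for f in range(n_families):
                acc = f"{sp}_fam{f+1}"
                records.append(SequenceRecord(id=acc, alphabet="protein",
                                              sequence=mutate_sequence(sp_ancestor, 0.9, rng)))
                family_of[acc] = f"fam{f+1}"
                species_of[acc] = sp
    else:
        raise ValueError("kind must be 'family' or 'species'")
    return records, family_of, species_of
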