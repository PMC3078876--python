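"""Synthetic two-library small-RNA data with planted ground truth.

The generator emulates the design of a two-condition (first-year vs
second-year crop; FP vs SP) small-RNA sequencing experiment at desk
scale: two libraries of collapsible 18-30 nt tags containing

* conserved miRNA families with known per-library abundances and known
  SP/FP fold-changes,
* novel miRNA loci embedded in a toy genome as inverted repeats whose
  fold satisfies the hairpin criteria,
* ncRNA contamination (fragments of rRNA/tRNA/snRNA/snoRNA references),
* low-frequency random noise tags standing in for the large unannotated
  fraction of real libraries.

Reads are emitted pre-trimmed and error-free: adapter ligation,
size-selection and base-call quality are wet-lab/instrument features the
downstream statistics never see. Library depth defaults to 1e5 reads,
which preserves the count-statistics structure of multi-million-read
libraries at testable cost; the miRNA read fraction is correspondingly
inflated so that per-miRNA expected counts span the same range as in deep
real libraries.

Every generated tag carries a truth label (category, source id, exact
per-library sampling probability), so each downstream stage can be tested
against planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from srnapipe.seqio import (
    RefRecord,
    revcomp,
    write_collapsed_fasta,
    write_fasta,
    write_fastq,
)
from srnapipe.tags import EmptyLibraryError

_NTS = np.array(list("ACGT"))

_GO_TERMS = {
    "biological_process": [
        "regulation of transcription",
        "plant development",
        "signal transduction",
        "response to stress",
        "metabolic process",
    ],
    "molecular_function": [
        "nucleic acid binding",
        "metal ion binding",
        "transcription factor activity",
        "ATP binding",
    ],
    "cellular_component": ["nucleus", "cytoplasm", "membrane", "plastid"],
}


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic experiment.

    Fractions partition each library's reads among tag sources; the
    conserved-miRNA pool receives the remainder
    ``1 - noise - ncrna - novel``. ``fold_change_map`` maps miRNA ids to
    their true SP/FP abundance ratio (linear scale); ids not generated yet
    may be filled in by the generator according to ``de_fraction`` (the
    share of conserved miRNAs given a true change, drawn from
    ``de_ratios``).
    """

    seed: int = 0
    n_conserved_families: int = 25
    n_novel_loci: int = 6
    fp_depth: int = 100_000
    sp_depth: int = 100_000
    fold_change_map: dict[str, float] | None = None
    noise_fraction: float = 0.50
    ncrna_fraction: float = 0.04
    novel_fraction: float = 0.02
    de_fraction: float = 0.30
    de_ratios: tuple[float, ...] = (4.0, 0.25, 2.0, 0.5)
    mature_len: int = 21
    stem_ext: int = 9
    loop_len: int = 8
    spacer_len: int = 150
    n_noise_tags: int = 4000
    n_ncrna_fragments: int = 150

    def __post_init__(self):
        fracs = (self.noise_fraction, self.ncrna_fraction, self.novel_fraction)
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("component fractions must lie in [0,1] and sum to <= 1")
        if self.fp_depth <= 0 or self.sp_depth <= 0:
            raise ValueError("library depths must be positive")
        if self.fold_change_map and any(r <= 0 for r in self.fold_change_map.values()):
            raise ValueError("fold-change ratios must be positive")
        if self.loop_len < 3 or self.stem_ext < 0 or self.spacer_len < 0 or self.mature_len < 15:
            raise ValueError("impossible hairpin/genome geometry")

    @property
    def conserved_fraction(self) -> float:
        return 1.0 - self.noise_fraction - self.ncrna_fraction - self.novel_fraction


@dataclass
class NovelLocus:
    """Coordinates of one planted hairpin locus on the toy genome."""

    locus_id: str
    genome_id: str
    precursor_start: int
    precursor_end: int  # exclusive
    mature_start: int
    mature_end: int  # exclusive
    strand: str
    precursor_seq: str
    mature_seq: str


@dataclass
class ReferenceBundle:
    """All reference files of one synthetic experiment."""

    ncrna: list[RefRecord]
    mirna: list[RefRecord]
    genome: list[tuple[str, str]]
    transcripts: list[tuple[str, str]]
    go_mapping: pd.DataFrame  # columns gene, ontology, term

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "ncrna": outdir / "ncrna.fasta",
            "mirna": outdir / "known_mirna.fasta",
            "genome": outdir / "genome.fasta",
            "transcripts": outdir / "transcripts.fasta",
            "go_mapping": outdir / "go_mapping.tsv",
        }
        write_fasta(
            [(f"{r.id}|{r.category}|{r.family}", r.seq) for r in self.ncrna], paths["ncrna"]
        )
        write_fasta(
            [(f"{r.id}|{r.category}|{r.family}", r.seq) for r in self.mirna], paths["mirna"]
        )
        write_fasta(self.genome, paths["genome"])
        write_fasta(self.transcripts, paths["transcripts"])
        self.go_mapping.to_csv(paths["go_mapping"], sep="\t", index=False, header=False)
        return paths


@dataclass
class PlantedTruth:
    """Ground truth of the synthetic experiment.

    ``tags`` has one row per plantable tag with its category
    (known_miRNA / novel_miRNA / ncRNA / noise), source id and the exact
    per-library sampling probability; expected counts are
    ``depth * probability``. ``fold_changes`` records the realized true
    SP/FP ratios; ``target_sites`` the planted complementarity sites with
    their expectation scores.
    """

    tags: pd.DataFrame
    novel_loci: list[NovelLocus]
    fold_changes: dict[str, float]
    target_sites: pd.DataFrame
    family_of: dict[str, str] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        self.tags.to_csv(path, sep="\t", index=False)


@dataclass
class LibraryPair:
    """Sampled read counts per tag for the two libraries."""

    counts_fp: dict[str, int]
    counts_sp: dict[str, int]

    def reads(self, library: str) -> list[str]:
        counts = self.counts_fp if library == "FP" else self.counts_sp
        out: list[str] = []
        for seq in sorted(counts):
            out.extend([seq] * counts[seq])
        return out

    def collapsed(self, library: str) -> list[tuple[str, int]]:
        counts = self.counts_fp if library == "FP" else self.counts_sp
        return sorted((s, c) for s, c in counts.items() if c > 0)

    def write(self, outdir: str | Path, fmt: str = "fasta") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for lib, counts in (("FP", self.counts_fp), ("SP", self.counts_sp)):
            if fmt == "fasta":
                path = outdir / f"{lib.lower()}_collapsed.fasta"
                write_collapsed_fasta({s: c for s, c in counts.items() if c > 0}, path)
            else:
                path = outdir / f"{lib.lower()}.fastq"
                write_fastq(self.reads(lib), path, prefix=f"{lib.lower()}_read")
            paths[lib] = path
        return paths


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_NTS, n))


def _loguniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    return 10 ** rng.uniform(np.log10(lo), np.log10(hi), n)


def _substring_pool(seqs, lengths=range(18, 31)) -> set[str]:
    pool = set()
    for s in seqs:
        for k in lengths:
            for i in range(len(s) - k + 1):
                pool.add(s[i : i + k])
    return pool


def _plant_site(rng: np.random.Generator, mature: str, variant: int) -> tuple[str, float, int]:
    """Build a target site for ``mature`` with a known penalty.

    Variants cycle through: 0 = perfect complement (expectation 0.0),
    1 = one central mismatch at miRNA position 10 (expectation 2.0,
    translational inhibition), 2 = one G:U outside the seed (0.5).
    Returns (site 5'->3', expectation, modified miRNA position or 0).
    """
    L = len(mature)
    site = list(revcomp(mature))  # site index L-i pairs miRNA position i
    if variant == 0:
        return "".join(site), 0.0, 0
    if variant == 1:
        i = 10
        m = mature[i - 1]
        # neither complement nor wobble partner of the miRNA base
        bad = {"A": "A", "C": "C", "G": "G", "T": "T"}[m]
        site[L - i] = bad
        return "".join(site), 2.0, i
    # one G:U wobble outside the seed (position > 13): need a G or T there
    for i in range(14, L + 1):
        m = mature[i - 1]
        if m == "G":
            site[L - i] = "T"
            return "".join(site), 0.5, i
        if m == "T":
            site[L - i] = "G"
            return "".join(site), 0.5, i
    return "".join(site), 0.0, 0  # no wobble-able base: fall back to perfect


def generate_reference_set(config: SimulationConfig) -> tuple[ReferenceBundle, PlantedTruth]:
    """Generate all reference files and the planted truth for one run.

    The toy genome embeds each novel locus as an inverted repeat (stem
    ``mature_len + stem_ext`` bp, loop ``loop_len`` nt) separated by random
    spacers; the transcript set contains one transcript per planted miRNA
    with a complementarity site of known penalty; the GO mapping assigns
    every transcript 1-3 terms. Identical seeds give identical bundles.
    """
    # independent streams: sequence content, fold-change assignment and
    # abundance weights do not perturb one another across config variants
    rng = np.random.default_rng([config.seed, 0])
    rng_fc = np.random.default_rng([config.seed, 2])
    rng_ab = np.random.default_rng([config.seed, 3])

    # --- ncRNA references -------------------------------------------------
    ncrna: list[RefRecord] = []
    for category, sizes in (
        ("rRNA", [600, 300]),
        ("tRNA", [75, 75, 74, 76]),
        ("snRNA", [160, 140, 150]),
        ("snoRNA", [100, 90, 110]),
    ):
        for j, size in enumerate(sizes, start=1):
            ncrna.append(RefRecord(f"{category}{j}", category, "", _rand_seq(rng, size)))
    forbidden = _substring_pool([r.seq for r in ncrna])

    # --- conserved miRNA families ----------------------------------------
    mirna: list[RefRecord] = []
    family_of: dict[str, str] = {}
    suffixes = "abcdefgh"
    for f in range(config.n_conserved_families):
        family = f"miR{101 + f}"
        n_members = int(rng.integers(2, 6))
        while True:
            consensus = _rand_seq(rng, int(rng.integers(20, 23)))
            if consensus not in forbidden:
                break
        members = []
        for m in range(n_members):
            seq = list(consensus)
            if m > 0:  # members are 1-substitution variants of the consensus
                pos = int(rng.integers(0, len(seq)))
                seq[pos] = str(rng.choice([c for c in "ACGT" if c != seq[pos]]))
            members.append("".join(seq))
        for m, seq in enumerate(dict.fromkeys(members)):  # drop accidental dups
            mid = f"rgl-{family}{suffixes[m]}"
            mirna.append(RefRecord(mid, "known_miRNA", family, seq))
            family_of[mid] = family
            forbidden.add(seq)

    # --- novel hairpin loci embedded in the toy genome --------------------
    arm_len = config.mature_len + config.stem_ext
    loci: list[NovelLocus] = []
    genome_parts = [_rand_seq(rng, config.spacer_len)]
    offset = config.spacer_len
    genome_id = "toygenome1"
    for i in range(config.n_novel_loci):
        while True:
            arm = _rand_seq(rng, arm_len)
            mature = arm[: config.mature_len]
            if mature not in forbidden:
                break
        precursor = arm + _rand_seq(rng, config.loop_len) + revcomp(arm)
        loci.append(
            NovelLocus(
                locus_id=f"rgl-nov{i + 1}",
                genome_id=genome_id,
                precursor_start=offset,
                precursor_end=offset + len(precursor),
                mature_start=offset,
                mature_end=offset + config.mature_len,
                strand="+",
                precursor_seq=precursor,
                mature_seq=mature,
            )
        )
        forbidden.add(mature)
        genome_parts.append(precursor)
        genome_parts.append(_rand_seq(rng, config.spacer_len))
        offset += len(precursor) + config.spacer_len
    genome_seq = "".join(genome_parts)
    # each mature must hit exactly its own locus per strand (the inverted
    # repeat puts it on the minus strand as well, by construction)
    for locus in loci:
        assert genome_seq.count(locus.mature_seq) == 1, "planted mature not unique in genome"
    genome = [(genome_id, genome_seq)]
    forbidden |= _substring_pool([genome_seq, revcomp(genome_seq)])

    # --- fold changes ------------------------------------------------------
    fold_changes: dict[str, float] = {}
    member_ids = [r.id for r in mirna]
    novel_ids = [l.locus_id for l in loci]
    if config.fold_change_map is not None:
        unknown = set(config.fold_change_map) - set(member_ids + novel_ids) - {"*"}
        if unknown:
            raise ValueError(f"fold_change_map names unknown miRNA ids: {sorted(unknown)}")
        default = config.fold_change_map.get("*", 1.0)  # "*" is a global override
        for mid in member_ids + novel_ids:
            fold_changes[mid] = config.fold_change_map.get(mid, default)
    else:
        for mid in member_ids:
            if rng_fc.random() < config.de_fraction:
                fold_changes[mid] = float(rng_fc.choice(config.de_ratios))
            else:
                fold_changes[mid] = 1.0
        for j, mid in enumerate(novel_ids):
            fold_changes[mid] = 4.0 if j < (len(novel_ids) + 1) // 2 else 1.0

    # --- transcripts with planted target sites ----------------------------
    transcripts: list[tuple[str, str]] = []
    site_rows = []
    for k, mid in enumerate(member_ids + novel_ids):
        mature = next(
            (r.seq for r in mirna if r.id == mid),
            next((l.mature_seq for l in loci if l.locus_id == mid), None),
        )
        variant = k % 3
        site, expectation, mod_pos = _plant_site(rng, mature, variant)
        left = _rand_seq(rng, 150)
        right = _rand_seq(rng, 150)
        gene = f"g_{mid}"
        transcripts.append((gene, left + site + right))
        site_rows.append(
            {
                "mirna": mid,
                "gene": gene,
                "site_start": 151,  # 1-based inclusive
                "site_end": 150 + len(site),
                "expectation": expectation,
                "modified_position": mod_pos,
                "mode": "translational_inhibition" if 9 <= mod_pos <= 11 and expectation > 0 else "cleavage",
            }
        )
    target_sites = pd.DataFrame(site_rows)

    # --- GO mapping --------------------------------------------------------
    go_rows = []
    for gene, _ in transcripts:
        for ontology in _GO_TERMS:
            if rng.random() < 0.7:
                term = str(rng.choice(_GO_TERMS[ontology]))
                go_rows.append({"gene": gene, "ontology": ontology, "term": term})
    go_mapping = pd.DataFrame(go_rows, columns=["gene", "ontology", "term"])

    # --- tag pool with per-library probabilities ---------------------------
    tag_rows = []

    def add_tags(seqs, ids, category, weights, fraction):
        w = np.asarray(weights, dtype=float)
        w_fp = w / w.sum() * fraction
        ratios = np.array([fold_changes.get(i, 1.0) for i in ids])
        w_sp_raw = w * ratios
        w_sp = w_sp_raw / w_sp_raw.sum() * fraction if w_sp_raw.sum() else w_sp_raw
        for seq, sid, pf, ps in zip(seqs, ids, w_fp, w_sp):
            tag_rows.append(
                {"sequence": seq, "category": category, "ref_id": sid, "prob_fp": pf, "prob_sp": ps}
            )

    add_tags(
        [r.seq for r in mirna],
        member_ids,
        "known_miRNA",
        _loguniform(rng_ab, 1.0, 3000.0, len(mirna)),
        config.conserved_fraction,
    )
    add_tags(
        [l.mature_seq for l in loci],
        novel_ids,
        "novel_miRNA",
        _loguniform(rng_ab, 1.0, 50.0, len(loci)),
        config.novel_fraction,
    )

    # ncRNA contamination fragments
    frag_seqs, frag_ids = [], []
    seen = set()
    while len(frag_seqs) < config.n_ncrna_fragments:
        ref = ncrna[int(rng.integers(0, len(ncrna)))]
        k = int(rng.integers(19, 29))
        i = int(rng.integers(0, len(ref.seq) - k + 1))
        frag = ref.seq[i : i + k]
        if frag in seen:
            continue
        seen.add(frag)
        frag_seqs.append(frag)
        frag_ids.append(ref.id)
    add_tags(
        frag_seqs,
        frag_ids,
        "ncRNA",
        _loguniform(rng_ab, 1.0, 100.0, len(frag_seqs)),
        config.ncrna_fraction,
    )

    # noise tags: uniform random, rejected on any reference collision, with
    # a length profile peaked at 24 nt (and a secondary 21 nt shoulder) as
    # seen in real plant small-RNA libraries
    length_probs = np.array([1, 1, 1, 4, 2, 2, 12, 3, 2, 1, 1, 1, 1], dtype=float)
    length_probs /= length_probs.sum()
    noise_seqs = []
    seen_noise = set(seen)
    while len(noise_seqs) < config.n_noise_tags:
        k = int(rng.choice(np.arange(18, 31), p=length_probs))
        seq = _rand_seq(rng, k)
        if seq in forbidden or seq in seen_noise:
            continue
        seen_noise.add(seq)
        noise_seqs.append(seq)
    add_tags(
        noise_seqs,
        [f"noise{i + 1}" for i in range(len(noise_seqs))],
        "noise",
        rng_ab.lognormal(0.0, 1.0, len(noise_seqs)),
        config.noise_fraction,
    )

    tags = pd.DataFrame(tag_rows)
    # renormalize exactly (guards against fractions summing slightly off 1)
    tags["prob_fp"] /= tags["prob_fp"].sum()
    tags["prob_sp"] /= tags["prob_sp"].sum()

    bundle = ReferenceBundle(ncrna, mirna, genome, transcripts, go_mapping)
    truth = PlantedTruth(tags, loci, fold_changes, target_sites, family_of)
    return bundle, truth


def sample_libraries(config: SimulationConfig, truth: PlantedTruth) -> LibraryPair:
    """Multinomially sample the two libraries from the planted truth.

    The expected count of tag t in library L is ``depth_L * prob_L(t)``;
    identical seeds give identical libraries.
    """
    if config.fp_depth <= 0 or config.sp_depth <= 0:
        raise EmptyLibraryError("library depth must be positive")
    rng = np.random.default_rng([config.seed, 1])
    seqs = truth.tags["sequence"].to_numpy()
    counts_fp = rng.multinomial(config.fp_depth, truth.tags["prob_fp"].to_numpy())
    counts_sp = rng.multinomial(config.sp_depth, truth.tags["prob_sp"].to_numpy())
    return LibraryPair(
        counts_fp={s: int(c) for s, c in zip(seqs, counts_fp) if c > 0},
        counts_sp={s: int(c) for s, c in zip(seqs, counts_sp) if c > 0},
    )
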