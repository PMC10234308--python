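"""Self-contained synthetic snoRNA cohorts for exercising the pipeline.

The generator emits everything the analysis consumes — genome FASTA, GTF
with host genes / introns / embedded snoRNAs, branchpoint TSV, replicate
TPM tables with a sample-to-tissue design, categorical metadata, and a
truth manifest — with the statistical structure the method assumes:

* snoRNA sequences carry their class motifs planted at canonical
  positions and degenerated by a controllable number of mutations;
* flanking sequences carry an engineered complementary block (0-15 nt)
  so the terminal-stem features are tunable;
* expression status follows a logistic model on the four driver features
  (box score, global stability, terminal-stem stability, host expression)
  *measured from the emitted files*, so imperfect planting cannot decouple
  features from labels; TPM tables are then written so that the >1 TPM
  labeling rule recovers the generated labels exactly.

A fixed seed yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import genome_io, motif_scoring, structure_features
from .genome_io import INTERGENIC

logger = logging.getLogger(__name__)

_RNA = "ACGU"
_RC = {"A": "U", "U": "A", "G": "C", "C": "G"}

HOST_FUNCTIONS = (
    "ribosomal_protein",
    "ribosome_biogenesis_translation",
    "rna_binding_processing_splicing",
    "functional_ncRNA",
    "nonfunctional_ncRNA",
    "other",
    "poorly_characterized",
)
TISSUE_PREFIX = "tissue"


@dataclass
class SyntheticConfig:
    """Generator knobs; defaults are the cohort conditions used throughout
    the test suite."""

    n_snornas: int = 200
    cd_fraction: float = 0.7
    intergenic_fraction: float = 0.3
    minus_strand_fraction: float = 0.5
    #: per-motif mutation count ~ geometric(p) - 1, truncated at motif length
    motif_mutation_p: float = 0.5
    stem_block_max: int = 15
    host_expressed_prob: float = 0.6
    host_protein_coding_prob: float = 0.6
    nmd_prob: float = 0.3
    dual_promoter_prob: float = 0.3
    target_probs: tuple[float, float, float] = (0.45, 0.10, 0.45)  # rRNA, snRNA, orphan
    #: logistic coefficients on class-relative (per-type z-scored) driver
    #: features; signs encode the observed directionality (degenerate boxes
    #: and unstable stems disfavor expression, H/ACA stability favors it,
    #: C/D stability slightly disfavors it, expressed hosts favor it)
    beta_box_score: float = -0.8
    beta_sno_stability_cd: float = 0.1
    beta_sno_stability_haca: float = -0.3
    beta_terminal_stem_stability: float = -0.5
    beta_host_expressed: float = 1.5
    #: global gain on the logit, set so the cohort's discriminability
    #: matches real snoRNA cohorts (Bayes AUC around 0.9)
    beta_gain: float = 2.5
    target_positive_fraction: float = 0.35
    label_noise: float = 0.05
    n_tissues: int = 7
    n_replicates: int = 3
    tpm_lognormal_mu: float = 2.0
    tpm_lognormal_sigma: float = 1.0
    replicate_sigma: float = 0.1
    folding_engine: str = "vienna"
    seed: int = 0

    def validate(self) -> None:
        for name in ("cd_fraction", "intergenic_fraction", "minus_strand_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate per tissue")
        if not 0 <= self.stem_block_max <= 15:
            raise ValueError("stem_block_max must be in [0, 15]")
        if self.intergenic_fraction >= 1 and self.beta_host_expressed != 0:
            raise ValueError(
                "infeasible config: fully intergenic cohort with a "
                "host-dependent expression coefficient"
            )


@dataclass
class CohortPaths:
    outdir: Path
    genome: Path
    gtf: Path
    branchpoints: Path
    metadata: Path
    sno_tpm: Path
    host_tpm: Path
    design: Path
    manifest: Path

    @classmethod
    def in_dir(cls, outdir: str | Path) -> "CohortPaths":
        d = Path(outdir)
        return cls(
            d,
            d / "genome.fa",
            d / "cohort.gtf",
            d / "branchpoints.tsv",
            d / "metadata.tsv",
            d / "snorna_tpm.tsv",
            d / "host_tpm.tsv",
            d / "design.tsv",
            d / "manifest.json",
        )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_RNA[k] for k in rng.integers(0, 4, n))


def _revcomp_rna(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


def _rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T")


def sample_degeneration(rng: np.random.Generator, p: float, cap: int) -> int:
    return int(min(rng.geometric(p) - 1, cap))


def _mutate_motif(motif: str, consensus: str, d: int, rng: np.random.Generator) -> str:
    """Mutate `d` distinct positions, preferring bases that violate the
    consensus at that position (impossible at N positions)."""
    out = list(motif)
    for pos in rng.choice(len(motif), size=min(d, len(motif)), replace=False):
        allowed = motif_scoring._IUPAC[consensus[pos]]
        violating = [b for b in _RNA if b not in allowed]
        pool = violating or [b for b in _RNA if b != out[pos]]
        out[pos] = pool[rng.integers(0, len(pool))]
    return "".join(out)


def generate_snorna(
    sno_type: str,
    degeneration: Mapping[str, int],
    rng: np.random.Generator,
    length: int | None = None,
) -> tuple[str, dict]:
    """A snoRNA sequence with class motifs planted at canonical positions
    then degenerated by the requested number of mutations per motif."""
    if sno_type == "CD":
        length = length or int(rng.integers(60, 121))
        c_off = int(rng.integers(3, 7))
        d_off = length - int(rng.integers(3, 7)) - 4
        mid = length // 2
        positions = {"C": c_off, "Dprime": mid - 8, "Cprime": mid, "D": d_off}
        # screen so a beyond-cap planted C box is not shadowed by an
        # accidental (or mutation-induced shifted) near-consensus window —
        # feasible for the 7-nt C motif; the short D/ACA motifs arise by
        # chance in any realistic background and are left unscreened
        d_c = int(degeneration.get("C", 0))
        for _attempt in range(100):
            plants = {}
            seq = list(_random_seq(rng, length))
            for kind, start in positions.items():
                cons = motif_scoring.CONSENSUS[kind]
                motif = cons.replace("R", "AG"[rng.integers(0, 2)]).replace("N", "A")
                d = int(degeneration.get(kind, 0))
                motif = _mutate_motif(motif, cons, d, rng)
                seq[start : start + len(motif)] = motif
                plants[kind] = {"start": start, "mutations": d, "sequence": motif}
            sequence = "".join(seq)
            c_hit = motif_scoring.find_c_box(sequence)
            if (d_c > motif_scoring.MISMATCH_CAPS["C"]) == (not c_hit.found):
                break
        else:  # pragma: no cover - vanishingly unlikely
            logger.warning("C-box background screen failed after 100 attempts")
        return sequence, plants
    if sno_type == "HACA":
        length = length or int(rng.integers(120, 161))
        seq = list(_random_seq(rng, length))
        plants = {}
        positions = {"H": length // 2, "ACA": length - 6}
        for kind, start in positions.items():
            cons = motif_scoring.CONSENSUS[kind]
            motif = cons.replace("N", _RNA[rng.integers(0, 4)])
            d = int(degeneration.get(kind, 0))
            motif = _mutate_motif(motif, cons, d, rng)
            seq[start : start + len(motif)] = motif
            plants[kind] = {"start": start, "mutations": d, "sequence": motif}
        return "".join(seq), plants
    raise ValueError(f"unknown snoRNA type {sno_type!r}")


def _engineer_flanks(
    rng: np.random.Generator, stem_block_len: int, flank_len: int = 15
) -> tuple[str, str]:
    """Random flanks whose stem-forming block is complementary: the first
    `stem_block_len` nt of the downstream flank reverse-complement the
    last `stem_block_len` nt of the upstream flank."""
    up = _random_seq(rng, flank_len)
    down = _random_seq(rng, flank_len)
    if stem_block_len:
        block = _revcomp_rna(up[-stem_block_len:])
        down = block + down[stem_block_len:]
    return up, down


@dataclass
class _Locus:
    chrom: str
    sequence: str  # DNA, plus-strand reference
    gtf_lines: list[str]
    branchpoints: list[dict]
    truth: dict


def _gtf_line(
    chrom: str,
    feature: str,
    start0: int,
    end0: int,
    strand: str,
    attrs: dict[str, str],
) -> str:
    attr_str = " ".join(f'{k} "{v}";' for k, v in attrs.items())
    return (
        f"{chrom}\tsynthetic\t{feature}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attr_str}"
    )


def generate_locus(
    sno_id: str,
    sno_seq: str,
    strand: str,
    stem_block_len: int,
    host: dict | None,
    rng: np.random.Generator,
) -> _Locus:
    """One chromosome holding a snoRNA (and its host gene when intronic).

    The locus is laid out in sense orientation and reverse-complemented
    as a whole for minus-strand loci, mirroring all coordinates.
    """
    margin = 50
    up_flank, down_flank = _engineer_flanks(rng, stem_block_len)
    chrom = f"chr_{sno_id}"
    truth: dict = {"stem_block_len": stem_block_len, "strand": strand}
    branchpoints: list[dict] = []
    features: list[tuple[str, int, int, dict]] = []  # (feature, start, end, attrs)

    if host is None:
        seq = _random_seq(rng, margin) + up_flank + sno_seq + down_flank
        seq += _random_seq(rng, margin)
        sno_start = margin + len(up_flank)
        sno_end = sno_start + len(sno_seq)
        truth["intron_context"] = None
        truth["host_id"] = None
    else:
        host_id = host["id"]
        n_introns = int(rng.integers(1, 7))
        sno_intron_idx = int(rng.integers(0, n_introns))  # 0-based, 5' order
        exon_lens = [int(rng.integers(80, 201)) for _ in range(n_introns + 1)]
        dist_up = int(rng.integers(20, 151))
        dist_down = int(rng.integers(50, 151))
        intron_lens = []
        for k in range(n_introns):
            if k == sno_intron_idx:
                intron_lens.append(dist_up + len(sno_seq) + dist_down)
            else:
                intron_lens.append(int(rng.integers(100, 301)))

        pieces = [_random_seq(rng, margin)]
        pos = margin
        exon_ivs, intron_ivs = [], []
        sno_start = sno_end = -1
        for k, ex_len in enumerate(exon_lens):
            pieces.append(_random_seq(rng, ex_len))
            exon_ivs.append((pos, pos + ex_len))
            pos += ex_len
            if k < n_introns:
                if k == sno_intron_idx:
                    pre = _random_seq(rng, dist_up - len(up_flank)) + up_flank
                    post = down_flank + _random_seq(rng, dist_down - len(down_flank))
                    pieces.append(pre)
                    sno_start = pos + dist_up
                    sno_end = sno_start + len(sno_seq)
                    pieces.append(sno_seq)
                    pieces.append(post)
                else:
                    pieces.append(_random_seq(rng, intron_lens[k]))
                intron_ivs.append((pos, pos + intron_lens[k]))
                pos += intron_lens[k]
        pieces.append(_random_seq(rng, margin))
        seq = "".join(pieces)

        gene_start, gene_end = exon_ivs[0][0], exon_ivs[-1][1]
        tx_id = f"{host_id}.t1"
        features.append(
            ("gene", gene_start, gene_end, {"gene_id": host_id, "gene_biotype": host["biotype"]})
        )
        features.append(
            (
                "transcript",
                gene_start,
                gene_end,
                {"gene_id": host_id, "transcript_id": tx_id, "gene_biotype": host["biotype"]},
            )
        )
        for es, ee in exon_ivs:
            features.append(
                (
                    "exon",
                    es,
                    ee,
                    {"gene_id": host_id, "transcript_id": tx_id, "gene_biotype": host["biotype"]},
                )
            )

        sno_intron = intron_ivs[sno_intron_idx]
        bp_offset = int(rng.integers(18, 45))
        bp_prob = float(rng.uniform(0.7, 1.0))
        branchpoints.append(
            {
                "pos": sno_intron[1] - bp_offset,  # sense-space point, 0-based
                "probability": round(bp_prob, 4),
                "intron_id": f"{tx_id}.intron{sno_intron_idx + 1}",
            }
        )
        if rng.random() < 0.5 and sno_intron[1] - sno_intron[0] > 120:
            decoy_offset = int(rng.integers(46, 100))
            branchpoints.append(
                {
                    "pos": sno_intron[1] - decoy_offset,
                    "probability": round(float(rng.uniform(0.05, 0.6)), 4),
                    "intron_id": f"{tx_id}.intron{sno_intron_idx + 1}",
                }
            )
        bp_dist_truth = abs((sno_intron[1] - bp_offset) - (sno_end - 1))
        truth["host_id"] = host_id
        truth["intron_context"] = {
            "total_introns": n_introns,
            "intron_length": intron_lens[sno_intron_idx],
            "rank_5p": sno_intron_idx + 1,
            "rank_3p": n_introns - sno_intron_idx,
            "relative_rank_3p": (n_introns - sno_intron_idx) / n_introns,
            "dist_upstream_exon": dist_up,
            "dist_downstream_exon": dist_down,
            "dist_branchpoint": bp_dist_truth,
        }

    features.append(
        ("gene", sno_start, sno_end, {"gene_id": sno_id, "gene_biotype": "snoRNA"})
    )
    features.append(
        (
            "transcript",
            sno_start,
            sno_end,
            {"gene_id": sno_id, "transcript_id": f"{sno_id}.t1", "gene_biotype": "snoRNA"},
        )
    )
    features.append(
        (
            "exon",
            sno_start,
            sno_end,
            {"gene_id": sno_id, "transcript_id": f"{sno_id}.t1", "gene_biotype": "snoRNA"},
        )
    )

    total = len(seq)
    if strand == "-":
        seq = _revcomp_rna(seq)
        features = [
            (feat, total - e, total - s, attrs) for feat, s, e, attrs in features
        ]
        for bp in branchpoints:
            bp["pos"] = total - 1 - bp["pos"]
        sno_start, sno_end = total - sno_end, total - sno_start

    gtf_lines = [
        _gtf_line(chrom, feat, s, e, strand, attrs) for feat, s, e, attrs in features
    ]
    for bp in branchpoints:
        bp.update(chrom=chrom, strand=strand)
    truth["sno_interval"] = [chrom, sno_start, sno_end, strand]
    return _Locus(chrom, _rna_to_dna(seq), gtf_lines, branchpoints, truth)


def _zscore(values: pd.Series) -> pd.Series:
    sd = values.std(ddof=0)
    return (values - values.mean()) / sd if sd > 0 else values * 0.0


def _logit_scores(measured: pd.DataFrame, config: SyntheticConfig) -> np.ndarray:
    """Logit of expression on class-relative driver features.

    Box score and global stability enter as z-scores within each snoRNA
    type (how conserved/stable a snoRNA is relative to its class), the
    terminal-stem stability as a global z-score, and host expression as
    its 0/1 indicator — so snoRNA class itself carries no label signal
    beyond the drivers, matching the observation that both classes share
    the same expression determinants.
    """
    by_type = measured.groupby("sno_type", group_keys=False)
    z_box = by_type["box_score"].apply(_zscore)
    z_sno = by_type["sno_stability"].apply(_zscore)
    z_stem = _zscore(measured["terminal_stem_stability"])
    beta_sno = np.where(
        measured["sno_type"] == "CD",
        config.beta_sno_stability_cd,
        config.beta_sno_stability_haca,
    )
    return config.beta_gain * (
        config.beta_box_score * z_box.loc[measured.index].to_numpy(float)
        + beta_sno * z_sno.loc[measured.index].to_numpy(float)
        + config.beta_terminal_stem_stability * z_stem.to_numpy(float)
        + config.beta_host_expressed * measured["host_expressed"].to_numpy(float)
    )


def generate_labels_and_tpm(
    measured: pd.DataFrame, config: SyntheticConfig, rng: np.random.Generator
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Labels from the logistic model on measured features, plus replicate
    TPM tables (snoRNA- and host-level) whose >1 TPM rule recovers the
    labels exactly.

    `measured` needs columns box_score, sno_stability,
    terminal_stem_stability, host_expressed (0/1), sno_type, host_id.
    Returns (labels, sno_tpm, host_tpm, design, probabilities frame).
    """
    s = _logit_scores(measured, config)
    intercept = brentq(
        lambda b: expit(s + b).mean() - config.target_positive_fraction, -100, 100
    )
    prob = expit(s + intercept)
    labels = (rng.random(len(prob)) < prob).astype(int)
    flipped = rng.random(len(prob)) < config.label_noise
    labels = np.where(flipped, 1 - labels, labels)
    labels = pd.Series(labels, index=measured.index, name="label")

    tissues = [f"{TISSUE_PREFIX}{t + 1}" for t in range(config.n_tissues)]
    samples = [f"{t}_rep{r + 1}" for t in tissues for r in range(config.n_replicates)]
    design = {f"{t}_rep{r + 1}": t for t in tissues for r in range(config.n_replicates)}

    def _tissue_means(expressed: bool) -> np.ndarray:
        if expressed:
            m = np.exp(
                rng.normal(config.tpm_lognormal_mu, config.tpm_lognormal_sigma, config.n_tissues)
            )
            if m.max() <= 1.0:
                m[rng.integers(config.n_tissues)] = 1.0 + np.exp(
                    rng.normal(config.tpm_lognormal_mu, config.tpm_lognormal_sigma)
                )
        else:
            m = rng.uniform(0.0, 0.9, config.n_tissues)
        return m

    def _replicates(means: np.ndarray) -> np.ndarray:
        reps = means[:, None] * np.exp(
            rng.normal(0.0, config.replicate_sigma, (len(means), config.n_replicates))
        )
        # rescale so replicate means equal the intended tissue means exactly
        with np.errstate(invalid="ignore"):
            scale = np.where(reps.mean(axis=1) > 0, means / reps.mean(axis=1), 0.0)
        return reps * scale[:, None]

    sno_rows, mean_rows = {}, {}
    for sno_id, label in labels.items():
        means = _tissue_means(bool(label))
        sno_rows[sno_id] = _replicates(means).ravel()
        mean_rows[sno_id] = means
    sno_tpm = pd.DataFrame.from_dict(sno_rows, orient="index", columns=samples)

    host_rows = {}
    host_status = measured.groupby("host_id")["host_expressed"].first()
    for host_id, expressed in host_status.items():
        if host_id is None or (isinstance(host_id, float) and np.isnan(host_id)):
            continue
        host_rows[host_id] = _replicates(_tissue_means(bool(expressed))).ravel()
    host_tpm = pd.DataFrame.from_dict(host_rows, orient="index", columns=samples)

    probs = pd.DataFrame(
        {"logit": s + intercept, "probability": prob, "flipped": flipped},
        index=measured.index,
    )
    return labels, sno_tpm, host_tpm, design, probs


def _measure_features(paths: CohortPaths, config: SyntheticConfig) -> pd.DataFrame:
    """Recompute the four driver features from the emitted files."""
    from pyfaidx import Fasta

    annotation = genome_io.read_annotation(paths.gtf)
    metadata = pd.read_csv(paths.metadata, sep="\t", index_col=0)
    fasta = Fasta(str(paths.genome))
    records = genome_io.read_snorna_records(
        annotation, fasta, metadata["sno_type"].to_dict()
    )
    engine = structure_features.get_engine(config.folding_engine)
    host_genes = [g for g in annotation.genes.values() if g.biotype != "snoRNA"]

    rows = []
    for rec in records:
        fold = structure_features.fold_global(rec.sequence, engine)
        score = motif_scoring.box_score(rec.sequence, rec.sno_type, fold.structure)
        up, down = genome_io.extract_flanks(rec, fasta)
        s5, s3 = structure_features.build_stem_strands(rec.sequence, rec.sno_type, up, down)
        duplex = structure_features.cofold_stem(s5, s3, engine)
        assignment = genome_io.assign_host(rec, host_genes)
        rows.append(
            {
                "sno_id": rec.id,
                "box_score": score.total,
                "sno_stability": fold.mfe,
                "terminal_stem_stability": duplex.mfe,
                "terminal_stem_length_score": structure_features.stem_length_score(duplex),
                "sno_type": rec.sno_type,
                "host_id": assignment.host_id,
            }
        )
    return pd.DataFrame(rows).set_index("sno_id")


def generate_cohort(
    config: SyntheticConfig, outdir: str | Path
) -> tuple[CohortPaths, dict]:
    """Generate a full cohort on disk; returns paths and the truth manifest."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    paths = CohortPaths.in_dir(outdir)
    paths.outdir.mkdir(parents=True, exist_ok=True)

    loci: list[_Locus] = []
    meta_rows = []
    host_truth: dict[str, int] = {}
    for i in range(config.n_snornas):
        sno_id = f"SNO{i:05d}"
        sno_type = "CD" if rng.random() < config.cd_fraction else "HACA"
        intergenic = rng.random() < config.intergenic_fraction
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        motifs = (
            motif_scoring.CD_MOTIFS if sno_type == "CD" else motif_scoring.HACA_MOTIFS
        )
        degeneration = {
            kind: sample_degeneration(
                rng, config.motif_mutation_p, motif_scoring.MOTIF_LENGTHS[kind]
            )
            for kind in motifs
        }
        seq, plants = generate_snorna(sno_type, degeneration, rng)
        stem_block = int(rng.integers(0, config.stem_block_max + 1))

        host = None
        meta = {
            "sno_id": sno_id,
            "sno_type": sno_type,
            "target": ("rRNA", "snRNA", "orphan")[
                rng.choice(3, p=np.asarray(config.target_probs) / sum(config.target_probs))
            ],
        }
        if intergenic:
            meta.update(
                host_biotype=INTERGENIC,
                host_function=INTERGENIC,
                nmd_susceptibility=INTERGENIC,
                dual_initiation_promoter=INTERGENIC,
            )
        else:
            host_id = f"HOST{i:05d}"
            protein = rng.random() < config.host_protein_coding_prob
            host = {"id": host_id, "biotype": "protein_coding" if protein else "lncRNA"}
            host_truth[host_id] = int(rng.random() < config.host_expressed_prob)
            meta.update(
                host_biotype="protein_coding" if protein else "noncoding",
                host_function=HOST_FUNCTIONS[rng.integers(0, len(HOST_FUNCTIONS))],
                nmd_susceptibility=(
                    "nmd_susceptible" if rng.random() < config.nmd_prob else "nmd_insensitive"
                ),
                dual_initiation_promoter=(
                    "dual_initiation"
                    if rng.random() < config.dual_promoter_prob
                    else "single_initiation"
                ),
            )
        meta_rows.append(meta)

        locus = generate_locus(sno_id, seq, strand, stem_block, host, rng)
        locus.truth.update(
            sno_type=sno_type,
            planted_motifs=plants,
            host_expressed=host_truth.get(locus.truth["host_id"], 0)
            if locus.truth["host_id"]
            else None,
        )
        loci.append(locus)

    # --- emit genome, annotation, branchpoints, metadata -------------------
    with open(paths.genome, "w") as fa:
        for locus in loci:
            fa.write(f">{locus.chrom}\n")
            for k in range(0, len(locus.sequence), 60):
                fa.write(locus.sequence[k : k + 60] + "\n")
    with open(paths.gtf, "w") as gtf:
        for locus in loci:
            gtf.write("\n".join(locus.gtf_lines) + "\n")
    bp_rows = [
        {
            "chrom": bp["chrom"],
            "pos": bp["pos"] + 1,  # 1-based on disk
            "strand": bp["strand"],
            "intron_id": bp["intron_id"],
            "probability": bp["probability"],
            "source": "synthetic",
        }
        for locus in loci
        for bp in locus.branchpoints
    ]
    pd.DataFrame(
        bp_rows, columns=["chrom", "pos", "strand", "intron_id", "probability", "source"]
    ).to_csv(paths.branchpoints, sep="\t", index=False)
    metadata = pd.DataFrame(meta_rows).set_index("sno_id")
    metadata.to_csv(paths.metadata, sep="\t")

    # --- measure driver features from the emitted files, then label -------
    measured = _measure_features(paths, config)
    measured["host_expressed"] = [
        host_truth.get(h, 0) if h else 0 for h in measured["host_id"]
    ]
    labels, sno_tpm, host_tpm, design, probs = generate_labels_and_tpm(
        measured, config, rng
    )
    sno_tpm.round(6).to_csv(paths.sno_tpm, sep="\t", index_label="gene_id")
    host_tpm.round(6).to_csv(paths.host_tpm, sep="\t", index_label="gene_id")
    pd.DataFrame(
        {"sample": list(design), "tissue": [design[s] for s in design]}
    ).to_csv(paths.design, sep="\t", index=False)

    manifest = {
        "config": dataclasses.asdict(config),
        "intercept": float(probs["logit"].iloc[0] - _logit_scores(measured, config)[0])
        if len(probs)
        else None,
        "snornas": {},
    }
    for locus in loci:
        sno_id = locus.truth["sno_interval"][0].removeprefix("chr_")
        manifest["snornas"][sno_id] = {
            **locus.truth,
            "label": int(labels[sno_id]),
            "probability": round(float(probs.loc[sno_id, "probability"]), 6),
            "flipped": bool(probs.loc[sno_id, "flipped"]),
            "measured": {
                k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in measured.loc[sno_id]
                .drop(["host_id"])
                .items()
            },
        }
    _validate_manifest(paths, manifest)
    with open(paths.manifest, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    return paths, manifest


def _validate_manifest(paths: CohortPaths, manifest: dict) -> None:
    """Cross-check emitted TPM tables against generated labels."""
    from .expression_labels import EXPRESSED, average_by_tissue, label_expression, read_design, read_tpm_table

    tpm = read_tpm_table(paths.sno_tpm)
    design = read_design(paths.design)
    relabeled = label_expression(average_by_tissue(tpm, design))
    for sno_id, truth in manifest["snornas"].items():
        derived = int(relabeled.loc[sno_id, "status"] == EXPRESSED)
        if derived != truth["label"]:
            raise AssertionError(
                f"manifest inconsistent with emitted TPM for {sno_id}: "
                f"label {truth['label']} vs derived {derived}"
            )
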