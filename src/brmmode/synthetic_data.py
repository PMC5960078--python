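"""Synthetic study generator with planted ground truth.

Generates a small genome, a gene annotation, ChIP IP/Input coverage, MNase
control/depleted coverage, an RNA-seq count matrix over the four study
conditions (dsGFP control, dsBRM depletion, dsBRM + wild-type rescue,
dsBRM + K804R rescue), and a truth table recording what was planted:

* BRM-bound genes carry IP/Input enrichment of a configurable fold over the
  gene body +/- 200 bp;
* target genes carry log2 fold-changes in the wild-type-rescue contrast, a
  configurable fraction of them concordantly in the mutant-rescue contrast
  (the ATPase-independence structure) and a small fraction also in the
  depletion-only contrast;
* counts are negative binomial with fixed dispersion;
* promoter windows carry TATAAA at class-specific frequencies;
* a subset of ATPase-independent genes ("cluster 1") gains gene-body
  nucleosome occupancy in the depleted MNase track, and every gene's
  TSS-upstream flank loses occupancy upon depletion.

All randomness flows from a single seed through spawned generator streams,
so identical configurations give byte-identical outputs. The module also
ships the fixed paper-count fixture: a 13,294-gene table of boolean/signed
flags whose marginal counts reproduce the published contingency table of the
original study.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome_model import (
    CONDITIONS,
    CountMatrix,
    CoverageTrack,
    GeneModel,
    write_annotation,
    write_bedgraph,
    write_counts,
)

__all__ = ["SimConfig", "SimStudy", "simulate_study", "write_study", "make_paper_fixture"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic study; the defaults mirror the study design."""

    n_genes: int = 400
    seed: int = 0
    # genome layout
    chrom: str = "chrS"
    intergenic_bp: int = 2500
    gene_length_median_bp: float = 3000.0
    gene_length_sigma: float = 1.0  # lognormal sigma; populates all 3 length classes
    min_gene_length_bp: int = 200
    # truth structure
    frac_bound: float = 0.40
    frac_target: float = 0.25  # of all genes; targets are a subset of bound genes
    frac_independent: float = 0.50  # of targets: concordant WT/mutant response
    frac_discordant: float = 0.0  # of targets: significant both ways, opposite sign
    frac_de_background: float = 0.10  # unbound genes DE in the WT contrast
    frac_depl_in_independent: float = 0.10  # independent genes also DE upon depletion
    frac_cluster1: float = 0.25  # of independent genes: strong nucleosome gain
    frac_down: float = 0.45  # share of planted effects that are repressive
    # expression model
    effect_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    depth: float = 1.0e6
    n_replicates: int = 2
    baseline_log_mean: float = 4.0  # lognormal abundance (natural-log scale)
    baseline_log_sigma: float = 1.0
    # ChIP model
    chip_enrichment_fold: float = 1.5
    chip_input_mean: float = 10.0
    chip_noise_cv: float = 0.05
    chip_flank_bp: int = 200
    # MNase model
    mnase_base: float = 1.0
    mnase_noise_cv: float = 0.10
    mnase_cluster1_delta: float = 1.5  # gene-body occupancy gain upon depletion
    mnase_flank_drop: float = 0.4  # fractional occupancy loss upstream of every TSS
    mnase_flank_bp: int = 500
    # promoter model
    tata_freq_dependent: float = 0.074
    tata_freq_independent: float = 0.093
    tata_freq_background: float = 0.19

    def __post_init__(self) -> None:
        for name in (
            "frac_bound", "frac_target", "frac_independent", "frac_discordant",
            "frac_de_background", "frac_depl_in_independent", "frac_cluster1",
            "frac_down", "tata_freq_dependent", "tata_freq_independent",
            "tata_freq_background",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_target > self.frac_bound:
            raise ValueError("frac_target cannot exceed frac_bound (targets are bound)")
        if self.frac_independent + self.frac_discordant > 1.0:
            raise ValueError("independent + discordant fractions exceed 1")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class SimStudy:
    """Everything one simulated study produces."""

    config: SimConfig
    genes: list[GeneModel]
    genome: dict[str, str]
    ip: CoverageTrack
    input_: CoverageTrack
    mnase_control: CoverageTrack
    mnase_depleted: CoverageTrack
    counts: CountMatrix
    truth: pd.DataFrame  # index gene_id; bound, de_wt, de_mut, de_depl,
    #                      atpase_class, tata_planted, cluster1


# ---------------------------------------------------------------------------


def _draw_gene_layout(cfg: SimConfig, rng: np.random.Generator):
    lengths = rng.lognormal(np.log(cfg.gene_length_median_bp), cfg.gene_length_sigma,
                            cfg.n_genes)
    lengths = np.maximum(lengths.astype(int), cfg.min_gene_length_bp)
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    genes: list[GeneModel] = []
    pos = cfg.intergenic_bp
    width = len(str(cfg.n_genes))
    for i in range(cfg.n_genes):
        gid = f"g{i:0{width}d}"
        genes.append(GeneModel(gid, cfg.chrom, pos, pos + int(lengths[i]), strands[i]))
        pos += int(lengths[i]) + cfg.intergenic_bp
    return genes, pos  # pos = genome length


def _assign_truth(cfg: SimConfig, genes: list[GeneModel], rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_genes
    ids = [g.gene_id for g in genes]
    n_bound = round(cfg.frac_bound * n)
    n_target = round(cfg.frac_target * n)
    n_indep = round(cfg.frac_independent * n_target)
    n_disc = round(cfg.frac_discordant * n_target)
    if n_indep + n_disc > n_target:
        raise ValueError("infeasible class fractions")

    perm = rng.permutation(n)
    bound_idx = perm[:n_bound]
    target_idx = bound_idx[:n_target]
    indep_idx = target_idx[:n_indep]
    disc_idx = target_idx[n_indep : n_indep + n_disc]
    unbound_idx = perm[n_bound:]
    n_bg = round(cfg.frac_de_background * len(unbound_idx))
    bg_de_idx = unbound_idx[:n_bg]

    truth = pd.DataFrame(
        {
            "bound": False,
            "de_wt": 0.0,
            "de_mut": 0.0,
            "de_depl": 0.0,
            "atpase_class": "none",
            "tata_planted": False,
            "cluster1": False,
        },
        index=pd.Index(ids, name="gene_id"),
    )
    truth.iloc[bound_idx, truth.columns.get_loc("bound")] = True

    sign = np.where(rng.random(n) < cfg.frac_down, -1.0, 1.0)
    fc = cfg.effect_log2fc
    arr_wt = truth["de_wt"].to_numpy()
    arr_mut = truth["de_mut"].to_numpy()
    arr_wt[target_idx] = sign[target_idx] * fc
    arr_wt[bg_de_idx] = sign[bg_de_idx] * fc
    arr_mut[indep_idx] = sign[indep_idx] * fc  # same direction: independent
    arr_mut[disc_idx] = -sign[disc_idx] * fc  # opposite: still dependent
    truth["de_wt"] = arr_wt
    truth["de_mut"] = arr_mut

    cls = truth["atpase_class"].to_numpy(dtype=object)
    cls[target_idx] = "dependent"
    cls[indep_idx] = "independent"
    truth["atpase_class"] = cls

    n_depl = round(cfg.frac_depl_in_independent * n_indep)
    depl_idx = indep_idx[:n_depl]
    arr_depl = truth["de_depl"].to_numpy()
    arr_depl[depl_idx] = sign[depl_idx] * fc
    truth["de_depl"] = arr_depl

    n_c1 = round(cfg.frac_cluster1 * n_indep)
    truth.iloc[indep_idx[:n_c1], truth.columns.get_loc("cluster1")] = True

    tata_p = np.full(n, cfg.tata_freq_background)
    tata_p[target_idx] = cfg.tata_freq_dependent
    tata_p[indep_idx] = cfg.tata_freq_independent
    truth["tata_planted"] = rng.random(n) < tata_p
    return truth


def _make_genome(cfg: SimConfig, genes, genome_len: int, truth: pd.DataFrame,
                 rng: np.random.Generator) -> dict[str, str]:
    seq = rng.choice(list("ACGT"), size=genome_len)
    # plant or scrub TATAAA in each -50/-10 promoter window (sense orientation)
    for g in genes:
        if g.strand == "+":
            lo, hi = g.tss - 50, g.tss - 10 + 1
        else:
            lo, hi = g.tss + 10, g.tss + 50 + 1
        lo, hi = max(0, lo), min(genome_len, hi)
        window = "".join(seq[lo:hi])
        sense = window if g.strand == "+" else _revcomp(window)
        if truth.loc[g.gene_id, "tata_planted"]:
            offset = int(rng.integers(0, len(sense) - 5))
            sense = sense[:offset] + "TATAAA" + sense[offset + 6 :]
        else:
            while "TATAAA" in sense:  # scrub accidental motifs
                i = sense.index("TATAAA")
                sense = sense[: i + 2] + "C" + sense[i + 3 :]
        seq[lo:hi] = list(sense if g.strand == "+" else _revcomp(sense))
    return {cfg.chrom: "".join(seq)}


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _block_noise(rng: np.random.Generator, n: int, cv: float, block: int = 200) -> np.ndarray:
    """Multiplicative gamma noise, piecewise constant over ``block``-bp windows."""
    if cv <= 0:
        return np.ones(n)
    nblocks = -(-n // block)
    shape = 1.0 / cv**2
    vals = rng.gamma(shape, 1.0 / shape, nblocks)
    return np.repeat(vals, block)[:n]


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def _make_chip_tracks(cfg: SimConfig, genes, genome_len, truth, rng):
    sizes = {cfg.chrom: genome_len}
    base = cfg.chip_input_mean * _block_noise(rng, genome_len, 0.3, block=1000)
    input_vec = _smooth(base, 500)
    fold = np.ones(genome_len)
    for g in genes:
        if truth.loc[g.gene_id, "bound"]:
            lo = max(0, g.start - cfg.chip_flank_bp)
            hi = min(genome_len, g.end + cfg.chip_flank_bp)
            fold[lo:hi] = cfg.chip_enrichment_fold
    ip_vec = input_vec * fold * _block_noise(rng, genome_len, cfg.chip_noise_cv)
    input_track = CoverageTrack(sizes)
    input_track.data[cfg.chrom] = input_vec
    ip_track = CoverageTrack(sizes)
    ip_track.data[cfg.chrom] = ip_vec
    return ip_track, input_track


def _make_mnase_tracks(cfg: SimConfig, genes, genome_len, truth, rng):
    sizes = {cfg.chrom: genome_len}
    ctrl = cfg.mnase_base * _block_noise(rng, genome_len, cfg.mnase_noise_cv)
    depl = cfg.mnase_base * _block_noise(rng, genome_len, cfg.mnase_noise_cv)
    for g in genes:
        if truth.loc[g.gene_id, "cluster1"]:
            depl[g.start : g.end] += cfg.mnase_cluster1_delta
        # nucleosome loss upstream of every TSS upon depletion
        if g.strand == "+":
            lo, hi = max(0, g.tss - cfg.mnase_flank_bp), g.tss
        else:
            lo, hi = g.tss + 1, min(genome_len, g.tss + 1 + cfg.mnase_flank_bp)
        depl[lo:hi] *= 1.0 - cfg.mnase_flank_drop
    control = CoverageTrack(sizes)
    control.data[cfg.chrom] = ctrl
    depleted = CoverageTrack(sizes)
    depleted.data[cfg.chrom] = depl
    return control, depleted


def _make_counts(cfg: SimConfig, truth: pd.DataFrame, rng: np.random.Generator) -> CountMatrix:
    n = len(truth)
    abundance = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sigma, n)
    rel = abundance / abundance.sum()
    effects = {
        "control": np.zeros(n),
        "dsBRM": truth["de_depl"].to_numpy(),
        "dsBRM_WT": truth["de_wt"].to_numpy(),
        "dsBRM_K804R": truth["de_mut"].to_numpy(),
    }
    nb_n = 1.0 / cfg.nb_dispersion
    cols, names, rows = [], [], []
    for cond in CONDITIONS:
        mu = cfg.depth * rel * np.power(2.0, effects[cond])
        for rep in range(1, cfg.n_replicates + 1):
            p = nb_n / (nb_n + mu)
            cols.append(rng.negative_binomial(nb_n, p))
            names.append(f"{cond}_r{rep}")
            rows.append((names[-1], cond, rep))
    counts = pd.DataFrame(
        np.column_stack(cols), index=truth.index, columns=names
    )
    samples = pd.DataFrame(rows, columns=["sample_id", "condition", "replicate"]).set_index(
        "sample_id"
    )
    mu_control = pd.Series(cfg.depth * rel, index=truth.index, name="mu_control")
    return CountMatrix(counts=counts, samples=samples), mu_control


def simulate_study(config: SimConfig) -> SimStudy:
    """Generate one full synthetic study from a config (deterministic per seed)."""
    streams = [np.random.default_rng(s) for s in
               np.random.SeedSequence(config.seed).spawn(6)]
    rng_layout, rng_truth, rng_genome, rng_chip, rng_mnase, rng_counts = streams
    genes, genome_len = _draw_gene_layout(config, rng_layout)
    truth = _assign_truth(config, genes, rng_truth)
    genome = _make_genome(config, genes, genome_len, truth, rng_genome)
    ip, input_ = _make_chip_tracks(config, genes, genome_len, truth, rng_chip)
    mn_ctrl, mn_depl = _make_mnase_tracks(config, genes, genome_len, truth, rng_mnase)
    counts, mu_control = _make_counts(config, truth, rng_counts)
    truth = truth.assign(mu_control=mu_control)
    return SimStudy(
        config=config,
        genes=genes,
        genome=genome,
        ip=ip,
        input_=input_,
        mnase_control=mn_ctrl,
        mnase_depleted=mn_depl,
        counts=counts,
        truth=truth,
    )


def write_study(study: SimStudy, outdir: str | Path) -> dict[str, Path]:
    """Write every study component in the text formats the readers accept."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"brmmode synthetic study config_hash={study.config.hash()}"
    paths = {
        "annotation": outdir / "genes.gff3",
        "genome": outdir / "genome.fa",
        "chrom_sizes": outdir / "genome.chrom.sizes",
        "ip": outdir / "chip_ip.bedGraph",
        "input": outdir / "chip_input.bedGraph",
        "mnase_control": outdir / "mnase_control.bedGraph",
        "mnase_depleted": outdir / "mnase_depleted.bedGraph",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.yaml",
    }
    write_annotation(study.genes, paths["annotation"], header=tag)
    with open(paths["genome"], "w") as fh:
        for chrom, seq in study.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom, n in study.ip.chrom_sizes.items():
            fh.write(f"{chrom}\t{n}\n")
    write_bedgraph(study.ip, paths["ip"], header=tag)
    write_bedgraph(study.input_, paths["input"], header=tag)
    write_bedgraph(study.mnase_control, paths["mnase_control"], header=tag)
    write_bedgraph(study.mnase_depleted, paths["mnase_depleted"], header=tag)
    write_counts(study.counts, paths["counts"], paths["samples"], header=tag)
    with open(paths["truth"], "w") as fh:
        fh.write(f"# {tag}\n")
        study.truth.to_csv(fh, sep="\t")
    study.config.to_yaml(paths["config"])
    return paths


# ---------------------------------------------------------------------------
# Paper-count fixture


#: Published marginal counts of the original study's classification.
PAPER_COUNTS = {
    "n_genes": 13294,
    "n_bound": 2521,
    "n_de_wt": 2112,
    "n_target": 541,
    "n_target_down": 245,
    "n_target_up": 296,
    "n_overlap_mut": 270,
    "n_concordant": 267,
    "n_independent": 267,
    "n_dependent": 274,
    "pct_independent": 49.35,
    "n_depl_in_independent": 24,
}


def make_paper_fixture() -> tuple[pd.DataFrame, dict]:
    """The fixed flag table replicating the published contingency counts.

    Returns a 13,294-gene table (bound, de_wt, de_mut, de_depl with signed
    calls in {-1, 0, +1}) plus the expected summary. Individual gene
    assignments are arbitrary but deterministic; only the marginals are
    meaningful: 2521 bound genes, 2112 genes responding to wild-type rescue,
    541 confident targets (245 down / 296 up), 270 of them also responding to
    the K804R mutant with 267 concordant (ATPase-independent; 49.35%), 274
    ATPase-dependent, and 24 of the 267 also responding to depletion alone.
    """
    c = PAPER_COUNTS
    n = c["n_genes"]
    ids = [f"fb{i:05d}" for i in range(n)]
    t = pd.DataFrame(
        {"bound": False, "de_wt": 0, "de_mut": 0, "de_depl": 0},
        index=pd.Index(ids, name="gene_id"),
    )
    n_indep = c["n_independent"]
    n_disc = c["n_overlap_mut"] - c["n_concordant"]
    n_target = c["n_target"]
    wt_sign = np.concatenate(
        [np.full(c["n_target_down"], -1), np.full(c["n_target_up"], 1)]
    )
    # rows 0..n_target-1: confident targets (independent first, then the
    # discordant pair+1, then mutant-silent dependent genes)
    t.iloc[:n_target, t.columns.get_loc("bound")] = True
    t.iloc[:n_target, t.columns.get_loc("de_wt")] = wt_sign
    t.iloc[:n_indep, t.columns.get_loc("de_mut")] = wt_sign[:n_indep]
    t.iloc[n_indep : n_indep + n_disc, t.columns.get_loc("de_mut")] = -wt_sign[
        n_indep : n_indep + n_disc
    ]
    t.iloc[: c["n_depl_in_independent"], t.columns.get_loc("de_depl")] = wt_sign[
        : c["n_depl_in_independent"]
    ]
    # bound but not responding to wild-type rescue
    n_bound_only = c["n_bound"] - n_target
    t.iloc[n_target : n_target + n_bound_only, t.columns.get_loc("bound")] = True
    # responding to wild-type rescue but not bound
    n_de_only = c["n_de_wt"] - n_target
    lo = c["n_bound"]
    sign = np.where(np.arange(n_de_only) % 2 == 0, 1, -1)
    t.iloc[lo : lo + n_de_only, t.columns.get_loc("de_wt")] = sign
    expected = dict(c)
    return t, expected
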