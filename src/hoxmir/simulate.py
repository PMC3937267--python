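"""Synthetic small-RNA-seq study generator with known ground truth.

Emulates the inputs of a case/control brain small-RNA study: a toy
genome carrying clustered miRNA hairpin loci laid out like the four Hox
clusters (including one mature name duplicated across two clusters, the
miR-196a situation), NB-distributed counts with planted condition fold
changes (several features at near-zero control expression), reads
re-expanded from counts with 3'-trimmed and 5'-shifted isomiR variants,
an appended 3' adapter and constructed low-quality reads, clinical
covariates drawn from a Gaussian copula with the study's correlation
structure, and triplicate qPCR CT tables consistent with a chosen fold
change under the 2^-ddCT model.

Every generator is a pure function of the configured seed: the same
seed yields byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .quant import MatureRecord, revcomp
from .reads import DEFAULT_ADAPTER, PHRED_OFFSET, Read
from .regions import GeneInterval


class SizingError(ValueError):
    """The locus layout does not fit in the configured genome."""


class ConfigurationError(ValueError):
    """An invalid simulation configuration (e.g. non-PSD correlations)."""


#: planted analogues of the five differentially expressed miRNAs:
#: name -> (baseline control mean, case/control fold change).  The
#: 10b/1247 analogues carry the published moderate-to-high control means
#: and fold changes; the 196a/196b/615 analogues are "near-zero control"
#: features (control mean <= 1) with large planted fold changes.
PLANTED_DE = {
    "miR-10b-like": (915.81, 28.41),
    "miR-1247-like": (49.44, 2.06),
    "miR-196a-like": (0.5, 55.0),
    "miR-196b-like": (1.0, 11.0),
    "miR-615-like": (0.5, 13.0),
}

#: default pairwise Pearson targets of the clinical copula
DEFAULT_CLINICAL_CORR = {
    ("onset_age", "death_age"): 0.85,
    ("cag", "onset_age"): -0.84,
    ("cag", "death_age"): -0.89,
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    The sample sizes (12 case / 9 control) and the planted fold-change
    analogues mirror the emulated study; the isomiR, adapter and quality
    settings are the fixed conditions under which the read-level modules
    are exercised.
    """

    n_case: int = 12
    n_control: int = 9
    cluster_layout: tuple = ((1, 15), (2, 15), (3, 15), (4, 15))
    mature_length: int = 22
    planted_fold_changes: dict = field(default_factory=dict)
    baseline_means: dict = field(default_factory=dict)
    dispersion: float = 0.05
    isomir_5p_shift_rate: float = 0.05
    isomir_3p_trim_rate: float = 0.20
    adapter: str = DEFAULT_ADAPTER
    low_quality_read_rate: float = 0.05
    duplicated_names: tuple = ("miR-196a-like",)
    plant_outlier: bool = False
    outlier_sample: str | None = None
    outlier_sigma: float = 2.0
    clinical_corr: dict = field(default_factory=lambda: dict(DEFAULT_CLINICAL_CORR))
    clinical_betas: dict = field(default_factory=lambda: {"cag": -0.18})
    mean_log_mu: float = math.log(100.0)
    mean_log_sigma: float = 1.5
    seed: int = 0

    @property
    def n_mirnas(self) -> int:
        return sum(k for _, k in self.cluster_layout)

    def validate(self) -> None:
        for name, rate in (
            ("isomir_5p_shift_rate", self.isomir_5p_shift_rate),
            ("isomir_3p_trim_rate", self.isomir_3p_trim_rate),
            ("low_quality_read_rate", self.low_quality_read_rate),
        ):
            if not 0 <= rate <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be positive")
        if any(m < 0 for m in self.baseline_means.values()):
            raise ConfigurationError("baseline means must be >= 0")
        if any(f <= 0 for f in self.planted_fold_changes.values()):
            raise ConfigurationError("planted fold changes must be > 0")
        if not self.cluster_layout:
            raise ConfigurationError("cluster_layout must be nonempty")

    def rng(self, stage: int) -> np.random.Generator:
        """Independent deterministic stream per generation stage."""
        return np.random.default_rng([self.seed, stage])


@dataclass
class Reference:
    genome: dict
    mature: list
    genes: list
    mature_seq: dict  # name -> mature-strand sequence


@dataclass
class GroundTruth:
    true_counts: pd.DataFrame
    conditions: pd.Series
    true_assignments: dict = field(default_factory=dict)
    true_outlier_samples: list = field(default_factory=list)
    true_glm_betas: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# reference


_LOCUS_SPACING = 120
_CLUSTER_GAP = 1500
_GENE_LEN = 300


def _mirna_names(config: SimulationConfig) -> list[str]:
    planted = list(PLANTED_DE)
    names: list[str] = []
    i = 0
    for cluster_id, k in config.cluster_layout:
        for j in range(k):
            if i < len(planted) and i < config.n_mirnas:
                names.append(planted[i])
            else:
                names.append(f"miR-sim{cluster_id}-{j + 1}")
            i += 1
    return names


def generate_reference(
    config: SimulationConfig, genome_length: int | None = None
) -> Reference:
    """Build the toy genome, mature annotation and gene table.

    Each mature miRNA gets a unique random sequence embedded at its
    annotated coordinates (verified to occur nowhere else on either
    strand); names listed in ``duplicated_names`` are embedded at a
    second locus in the next cluster.  Each cluster is bracketed by a
    pair of flanking Hox-like boundary genes.
    """
    config.validate()
    rng = config.rng(1)
    L = config.mature_length
    names = _mirna_names(config)

    # lay out loci cluster by cluster
    loci: list[tuple[str, int, str, int]] = []  # (name, cluster, strand, start)
    pos = _CLUSTER_GAP
    cluster_bounds: dict[int, list[int]] = {}
    idx = 0
    extra: list[tuple[str, int]] = []  # duplicated names to re-embed later
    for ci, (cluster_id, k) in enumerate(config.cluster_layout):
        start_pos = pos
        for j in range(k):
            name = names[idx]
            strand = "+" if rng.random() < 0.5 else "-"
            loci.append((name, cluster_id, strand, pos))
            if name in config.duplicated_names:
                extra.append((name, ci))
            pos += _LOCUS_SPACING
            idx += 1
        cluster_bounds[cluster_id] = [start_pos, pos]
        pos += _CLUSTER_GAP
    # second locus for duplicated names, appended inside the next cluster
    for name, ci in extra:
        target_cluster = config.cluster_layout[(ci + 1) % len(config.cluster_layout)][0]
        strand = "+" if rng.random() < 0.5 else "-"
        start = cluster_bounds[target_cluster][1]
        loci.append((name, target_cluster, strand, start))
        cluster_bounds[target_cluster][1] = start + _LOCUS_SPACING
        pos = max(pos, start + _LOCUS_SPACING + _CLUSTER_GAP)

    required = pos + _CLUSTER_GAP
    if genome_length is None:
        genome_length = required
    if genome_length < required:
        raise SizingError(
            f"layout needs {required} bp but genome_length is {genome_length}"
        )

    alphabet = np.array(list("ACGT"))
    genome = rng.integers(0, 4, size=genome_length)
    genome_chars = alphabet[genome]

    # embed unique mature sequences, re-drawing on (rare) collisions
    mature_seq: dict[str, str] = {}
    records: list[MatureRecord] = []
    for name, cluster_id, strand, start in loci:
        if name not in mature_seq:
            mature_seq[name] = "".join(alphabet[rng.integers(0, 4, size=L)])
        segment = mature_seq[name] if strand == "+" else revcomp(mature_seq[name])
        genome_chars[start : start + L] = list(segment)
        records.append(MatureRecord(name, "chrSim", start, start + L, strand))

    seq = "".join(genome_chars)
    for _ in range(50):
        seq, mature_seq, ok = _verify_unique(seq, records, mature_seq, rng, L, alphabet)
        if ok:
            break
    else:  # pragma: no cover - vanishingly unlikely
        raise SizingError("could not embed unique mature sequences")

    genes = _gene_table(config, cluster_bounds, genome_length)
    return Reference({"chrSim": seq}, records, genes, mature_seq)


def _verify_unique(seq, records, mature_seq, rng, L, alphabet):
    """Check every mature sequence occurs only at its annotated loci."""
    chars = None
    ok = True
    by_name: dict[str, list[MatureRecord]] = {}
    for r in records:
        by_name.setdefault(r.name, []).append(r)
    for name, recs in by_name.items():
        s = mature_seq[name]
        n_fwd = seq.count(s)
        n_rev = seq.count(revcomp(s)) if revcomp(s) != s else 0
        expect_fwd = sum(1 for r in recs if r.strand == "+")
        expect_rev = sum(1 for r in recs if r.strand == "-")
        if n_fwd != expect_fwd or n_rev != expect_rev:
            ok = False
            if chars is None:
                chars = list(seq)
            new = "".join(alphabet[rng.integers(0, 4, size=L)])
            mature_seq[name] = new
            for r in recs:
                segment = new if r.strand == "+" else revcomp(new)
                chars[r.start : r.end] = list(segment)
    if chars is not None:
        seq = "".join(chars)
    return seq, mature_seq, ok


def _gene_table(config, cluster_bounds, genome_length) -> list[GeneInterval]:
    genes = []
    for cluster_id, (lo, hi) in cluster_bounds.items():
        # flanking boundary genes sit just outside the miRNA loci but
        # well inside the inter-cluster gap, so adjacent clusters'
        # bracketing intervals never overlap
        genes.append(
            GeneInterval(
                f"HOXSIM{cluster_id}-1", "chrSim",
                max(1, lo - _GENE_LEN - 100), max(2, lo - 100), "+",
            )
        )
        genes.append(
            GeneInterval(
                f"HOXSIM{cluster_id}-13", "chrSim",
                hi + 100, hi + 100 + _GENE_LEN, "+",
            )
        )
        # interior Hox-like genes between the boundary pair
        mid = (lo + hi) // 2
        genes.append(
            GeneInterval(
                f"HOXSIM{cluster_id}-5", "chrSim", mid, mid + _GENE_LEN, "-",
            )
        )
    # a distal non-cluster gene
    genes.append(
        GeneInterval("DISTAL-1", "chrSim", genome_length - _GENE_LEN,
                     genome_length, "+")
    )
    return genes


# ---------------------------------------------------------------------------
# counts


def _nb_draw(rng, mu, alpha, size):
    mu = np.broadcast_to(np.asarray(mu, dtype=float), size)
    out = np.zeros(size, dtype=np.int64)
    pos = mu > 0
    if alpha <= 1e-12:
        out[pos] = rng.poisson(mu[pos])
    else:
        n = 1.0 / alpha
        p = n / (n + mu[pos])
        out[pos] = rng.negative_binomial(n, p)
    return out


def sample_ids(config: SimulationConfig) -> tuple[list[str], pd.Series]:
    cases = [f"case{i + 1:02d}" for i in range(config.n_case)]
    controls = [f"ctrl{i + 1:02d}" for i in range(config.n_control)]
    samples = controls + cases
    cond = pd.Series(
        ["control"] * len(controls) + ["case"] * len(cases), index=samples,
        name="condition",
    )
    return samples, cond


def simulate_counts(
    config: SimulationConfig, reference: Reference
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw the NB count matrix with planted condition fold changes.

    Control counts are NB(baseline mean, dispersion); case counts use
    the baseline scaled by the planted fold change (1 where none is
    planted).  When ``plant_outlier`` is set, one control sample is
    displaced in expression space by per-feature log-normal scaling.
    """
    config.validate()
    rng = config.rng(2)
    names = list(dict.fromkeys(r.name for r in reference.mature))
    baselines = dict(config.baseline_means)
    fcs = dict(config.planted_fold_changes)
    for name in names:
        if name not in baselines:
            if name in PLANTED_DE:
                baselines[name] = PLANTED_DE[name][0]
            else:
                baselines[name] = float(
                    np.exp(rng.normal(config.mean_log_mu, config.mean_log_sigma))
                )
        if name not in fcs:
            fcs[name] = PLANTED_DE[name][1] if name in PLANTED_DE else 1.0

    samples, cond = sample_ids(config)
    counts = np.zeros((len(names), len(samples)), dtype=np.int64)
    for i, name in enumerate(names):
        mu = np.array(
            [
                baselines[name] * (fcs[name] if cond[s] == "case" else 1.0)
                for s in samples
            ]
        )
        counts[i] = _nb_draw(rng, mu, config.dispersion, (len(samples),))
    matrix = pd.DataFrame(counts, index=names, columns=samples)

    outliers: list[str] = []
    if config.plant_outlier:
        target = config.outlier_sample or samples[0]  # first control
        scale = np.exp(rng.normal(0.0, config.outlier_sigma, size=len(names)))
        matrix[target] = np.round(matrix[target].to_numpy() * scale).astype(np.int64)
        outliers = [target]

    truth = GroundTruth(
        true_counts=matrix.copy(),
        conditions=cond,
        true_outlier_samples=outliers,
        true_glm_betas=dict(config.clinical_betas),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# reads


def counts_to_reads(
    counts: pd.DataFrame,
    reference: Reference,
    config: SimulationConfig,
) -> tuple[dict, dict]:
    """Expand each count unit into one adapter-bearing read.

    Per unit: a locus of the miRNA is chosen (uniformly for duplicated
    names), the genomic window is optionally 5'-shifted by +-1
    (``isomir_5p_shift_rate``; these reads are unassignable under the
    5'-anchor rule and carry ground truth None) or 3'-trimmed by 1-3 nt
    (``isomir_3p_trim_rate``; ground truth keeps the miRNA), the full 3'
    adapter is appended and Phred+33 qualities are generated.  A
    ``low_quality_read_rate`` fraction of reads is constructed to fail
    the >= 80% >= Q20 rule by margin (30% of bases at Q <= 10).

    Returns (reads by sample, read id -> mature name or None).
    """
    config.validate()
    rng = config.rng(3)
    chrom_seq = reference.genome["chrSim"]
    loci_by_name: dict[str, list[MatureRecord]] = {}
    for rec in reference.mature:
        loci_by_name.setdefault(rec.name, []).append(rec)
    missing = set(counts.index) - set(loci_by_name)
    if missing:
        raise ValueError(f"counted miRNAs not in reference: {sorted(missing)}")

    reads_by_sample: dict[str, list[Read]] = {}
    truth: dict[str, str | None] = {}
    for sample in counts.columns:
        reads: list[Read] = []
        ridx = 0
        for name in counts.index:
            n = int(counts.loc[name, sample])
            for _ in range(n):
                recs = loci_by_name[name]
                rec = recs[int(rng.integers(len(recs)))] if len(recs) > 1 else recs[0]
                start, end = rec.start, rec.end
                shifted = rng.random() < config.isomir_5p_shift_rate
                if shifted:
                    d = 1 if rng.random() < 0.5 else -1
                    start, end = start + d, end + d
                elif rng.random() < config.isomir_3p_trim_rate:
                    t = int(rng.integers(1, 4))
                    if rec.strand == "+":
                        end -= t
                    else:
                        start += t
                window = chrom_seq[start:end]
                insert = window if rec.strand == "+" else revcomp(window)
                seq = insert + config.adapter
                qual = _qualities(rng, len(seq), config.low_quality_read_rate)
                read_id = f"{sample}:r{ridx:07d}"
                reads.append(Read(read_id, seq, qual))
                truth[read_id] = None if shifted else name
                ridx += 1
        reads_by_sample[sample] = reads
    return reads_by_sample, truth


def _qualities(rng, length: int, low_quality_rate: float) -> str:
    q = rng.integers(32, 41, size=length)
    if rng.random() < low_quality_rate:
        n_low = math.ceil(0.3 * length)  # fails the 80% >= Q20 rule by margin
        pos = rng.choice(length, size=n_low, replace=False)
        q[pos] = rng.integers(2, 11, size=n_low)
    return "".join(chr(int(v) + PHRED_OFFSET) for v in q)


# ---------------------------------------------------------------------------
# clinical covariates


def _copula_corr_matrix(corr: dict) -> tuple[list[str], np.ndarray]:
    vars_ = ["cag", "onset_age", "death_age"]
    R = np.eye(3)
    for (a, b), r in corr.items():
        if a not in vars_ or b not in vars_:
            raise ConfigurationError(f"unknown clinical variable pair ({a}, {b})")
        i, j = vars_.index(a), vars_.index(b)
        R[i, j] = R[j, i] = r
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ConfigurationError("target correlation matrix is not PSD")
    return vars_, R


def simulate_clinical(
    config: SimulationConfig, n: int | None = None
) -> pd.DataFrame:
    """Case clinical covariates from a Gaussian copula.

    CAG, onset age and death age carry the configured pairwise Pearson
    targets (defaults: onset-death +0.85, CAG-onset -0.84, CAG-death
    -0.89); disease duration, PMI and RIN are generated independently.
    Copula normals are mapped monotonically to realistic ranges (CAG
    integers 40-52, onset 25-65, death 35-80 years).
    """
    config.validate()
    rng = config.rng(4)
    if n is None:
        n = config.n_case
    vars_, R = _copula_corr_matrix(config.clinical_corr)
    chol = np.linalg.cholesky(R + 1e-12 * np.eye(3))
    z = rng.standard_normal((n, 3)) @ chol.T
    from scipy.stats import norm

    u = norm.cdf(z)
    cag = 40 + np.minimum(12, np.floor(u[:, 0] * 13).astype(int))
    onset = 25 + u[:, 1] * 40
    death = 35 + u[:, 2] * 45
    duration = 5 + rng.random(n) * 20
    pmi = 4 + rng.random(n) * 30
    rin = 6 + rng.random(n) * 2.5
    return pd.DataFrame(
        {
            "cag": cag,
            "onset_age": np.round(onset, 1),
            "death_age": np.round(death, 1),
            "duration": np.round(duration, 1),
            "pmi": np.round(pmi, 1),
            "rin": np.round(rin, 2),
            "condition": "case",
        },
        index=[f"case{i + 1:02d}" for i in range(n)],
    ).rename_axis("sample")


def simulate_glm_response(
    covariates: pd.DataFrame,
    betas: dict,
    dispersion: float = 0.05,
    target_mean: float = 1000.0,
    intercept: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """NB counts with log-linear dependence on covariates.

    The intercept defaults to centering the linear predictor so the
    geometric-mean response equals ``target_mean``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    eta = np.zeros(len(covariates))
    for name, beta in betas.items():
        eta += beta * covariates[name].to_numpy(dtype=float)
    if intercept is None:
        intercept = math.log(target_mean) - eta.mean()
    mu = np.exp(intercept + eta)
    return _nb_draw(rng, mu, dispersion, (len(covariates),))


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr(
    config: SimulationConfig,
    fold_changes: dict,
    n_case: int = 8,
    n_control: int = 8,
    reference_assay: str = "RNU48-like",
    noise_sd: float = 0.1,
    n_replicates: int = 3,
    base_ct_reference: float = 20.0,
    base_dct: float = 5.0,
):
    """Triplicate CT tables consistent with given fold changes.

    For case samples CT_target = CT_reference + base_dct - log2(FC);
    every well adds Gaussian replicate noise of SD ``noise_sd`` cycles.
    Inverting the 2^-ddCT arithmetic on this table recovers the planted
    fold changes (exactly at zero noise).
    """
    from .qpcr import CtRecord

    if any(fc <= 0 for fc in fold_changes.values()):
        raise ConfigurationError("fold changes must be > 0")
    rng = config.rng(5)
    records: list[CtRecord] = []
    samples = [("control", f"qc{i + 1:02d}") for i in range(n_control)] + [
        ("case", f"qh{i + 1:02d}") for i in range(n_case)
    ]
    for condition, sample in samples:
        ct_ref = base_ct_reference + rng.normal(0, 0.5)
        records.append(
            CtRecord(
                sample, condition, reference_assay,
                tuple(ct_ref + rng.normal(0, noise_sd) for _ in range(n_replicates)),
            )
        )
        for assay, fc in fold_changes.items():
            shift = -math.log2(fc) if condition == "case" else 0.0
            ct_t = ct_ref + base_dct + shift
            records.append(
                CtRecord(
                    sample, condition, assay,
                    tuple(ct_t + rng.normal(0, noise_sd) for _ in range(n_replicates)),
                )
            )
    return records


# ---------------------------------------------------------------------------
# bundle


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    reference: Reference
    counts: pd.DataFrame
    truth: GroundTruth
    reads_by_sample: dict | None = None
    clinical: pd.DataFrame | None = None


def simulate_dataset(
    config: SimulationConfig,
    with_reads: bool = False,
    with_clinical: bool = True,
) -> SimulatedDataset:
    """Generate the full study bundle under one seed."""
    reference = generate_reference(config)
    counts, truth = simulate_counts(config, reference)
    reads = None
    if with_reads:
        reads, assignments = counts_to_reads(counts, reference, config)
        truth.true_assignments = assignments
    clinical = simulate_clinical(config) if with_clinical else None
    return SimulatedDataset(config, reference, counts, truth, reads, clinical)
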