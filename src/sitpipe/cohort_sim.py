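"""Synthetic study generator with known ground truth.

Emulates the study design the pipeline targets: 38 situs inversus cases
and 38 matched controls recruited in two stages, half of the cases
carrying a planted causal genotype in a candidate gene (a mixture of
homozygous-recessive, compound-heterozygous, X-linked hemizygous and
dominant configurations), rare background variation shared across cases
and controls to exercise the control-subtraction step, two sibling pairs
planted in the kinship genotype matrix, and brain-asymmetry phenotypes in
which the case groups differ from controls on torque metrics and sinus
volumes (identically for genetically solved and unsolved cases) while
functional laterality shows no group effect.

Every planted causal variant is constructed to pass the full variant
filter cascade, and planted genes never appear in controls, so with the
default configuration the prioritization stage recovers the planted
solved set exactly. All randomness flows from one integer seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .group_stats import count_atypical
from .io_formats import AnnotatedVariant, CandidateGene, Individual, PhenotypeRecord, SiteMetrics

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_sib_genotypes",
    "simulate_phenotypes",
]

_MODELS = ("recessive_hom", "compound_het", "x_linked", "dominant")

LI_TASKS = ("li_word", "li_praxis", "li_spatial", "li_face")
# Task-typical signed means (positive = rightward): speech and praxis are
# left-lateralized in most people, spatial attention and face recognition
# right-lateralized.
_LI_TYPICAL_MEAN = {"li_word": -1.5, "li_praxis": -1.2, "li_spatial": 1.0, "li_face": 0.8}
_LI_SD = 0.5

TORQUE_METRICS = ("frontal_petalia", "frontal_bending", "occipital_petalia", "occipital_bending")
_TORQUE_SD = 1.0
_SINUS_MEAN, _SINUS_SD = 300.0, 60.0

_NOMINAL_SITE = SiteMetrics(qd=25.0, fs=0.5, mq=60.0, haplotype_score=2.0,
                            mq_rank_sum=0.1, read_pos_rank_sum=0.1)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    The default effect sizes are the standardized case-vs-control
    differences the study design embodies: strong reversals of occipital
    bending (1.05) and occipital petalia (0.90), a moderate frontal
    petalia effect (0.70), no frontal bending effect, a 0.5 SD sinus
    volume effect, and no group effect on any functional laterality index.
    """

    n_cases: int = 38
    n_controls: int = 38
    n_solved_target: int = 19
    model_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "recessive_hom": 0.35,
            "compound_het": 0.45,
            "x_linked": 0.05,
            "dominant": 0.15,
        }
    )
    background_gene_pool: int = 500
    n_candidate_genes: int = 40
    rare_af_range: tuple[float, float] = (1e-6, 5e-3)
    n_kinship_snps: int = 5000
    n_sib_pairs: int = 2
    phenotype_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "frontal_petalia": 0.70,
            "frontal_bending": 0.0,
            "occipital_petalia": 0.90,
            "occipital_bending": 1.05,
            "sinus": 0.5,
            "li_word": 0.0,
            "li_praxis": 0.0,
            "li_spatial": 0.0,
            "li_face": 0.0,
        }
    )
    atypical_flip_prob: Mapping[str, float] = field(
        default_factory=lambda: {"control": 0.08, "case": 0.15}
    )
    chet_phase_cis: bool = False
    n_shared_chet_genes: int = 3
    n_notable_cases: int = 2
    mean_background_variants: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.model_mix.values()) - 1.0) > 1e-9:
            raise ValueError("model_mix proportions must sum to 1")
        if self.n_solved_target > self.n_cases:
            raise ValueError("n_solved_target may not exceed n_cases")

    def model_counts(self) -> dict[str, int]:
        """Deterministic largest-remainder apportionment of solved cases."""
        raw = {m: self.n_solved_target * self.model_mix[m] for m in _MODELS}
        counts = {m: math.floor(raw[m]) for m in _MODELS}
        short = self.n_solved_target - sum(counts.values())
        by_rem = sorted(_MODELS, key=lambda m: raw[m] - counts[m], reverse=True)
        for m in by_rem[:short]:
            counts[m] += 1
        return counts


@dataclass(frozen=True)
class GroundTruth:
    solved: dict[str, tuple[str, str]]  # individual -> (gene, model)
    group_labels: dict[str, str]  # individual -> solved | unsolved | control
    sib_pairs: tuple[tuple[str, str], ...]
    group_means: dict[str, dict[str, float]]


@dataclass(frozen=True)
class SimulatedCohort:
    individuals: list[Individual]
    variants: dict[str, list[AnnotatedVariant]]
    candidates: list[CandidateGene]
    genotype_matrix: pd.DataFrame
    variant_freqs: pd.Series
    phenotypes: list[PhenotypeRecord]
    ground_truth: GroundTruth


def _log_uniform(rng: np.random.Generator, low: float, high: float) -> float:
    return float(np.exp(rng.uniform(np.log(low), np.log(high))))


class _VariantFactory:
    """Builds filter-passing (or deliberately failing) annotated variants
    with unique synthetic coordinates."""

    def __init__(self, rng: np.random.Generator, gene_chrom: Mapping[str, str],
                 af_range: tuple[float, float]):
        self.rng = rng
        self.gene_chrom = gene_chrom
        self.af_range = af_range
        self._pos = 10_000

    def _next_pos(self) -> int:
        self._pos += int(self.rng.integers(50, 500))
        return self._pos

    def causal(self, iid: str, gene: str, zygosity: str, max_af: float,
               phased_cis: bool = False) -> AnnotatedVariant:
        """A variant guaranteed to pass every filter rule."""
        rng = self.rng
        rescue = rng.random() < 0.2
        if rescue:
            csq, cadd, am = "missense", float(rng.uniform(2, 19)), "pathogenic"
        else:
            csq = str(rng.choice(["missense", "stop_gain", "frameshift", "splicing"]))
            cadd = float(rng.uniform(22, 45))
            am = "pathogenic" if csq == "missense" and rng.random() < 0.5 else None
        is_indel = csq == "frameshift"
        dp = int(rng.integers(20, 41))
        if zygosity == "het":
            ad_alt = int(rng.integers(math.ceil(dp * 0.3), math.floor(dp * 0.7) + 1))
            ad_ref = dp - ad_alt
        elif zygosity == "hom":
            ad_ref, ad_alt = 0, dp
        else:  # hemi
            ad_ref, ad_alt = 0, dp
        af = None if rng.random() < 0.2 else _log_uniform(rng, self.af_range[0], max_af)
        return AnnotatedVariant(
            individual_id=iid,
            chrom=self.gene_chrom[gene],
            pos=self._next_pos(),
            ref="ATT" if is_indel else "A",
            alt="A" if is_indel else "G",
            gene=gene,
            consequence=csq,
            zygosity=zygosity,
            dp=dp,
            gq=int(rng.integers(40, 100)),
            ad_ref=ad_ref,
            ad_alt=ad_alt,
            splice_distance=int(rng.integers(1, 3)) if csq == "splicing" else None,
            cadd=cadd,
            am_class=am,
            af=af,
            site=_NOMINAL_SITE,
            phased_cis=phased_cis,
        )

    def background(self, iid: str, gene: str) -> AnnotatedVariant:
        """A random rare heterozygous background variant; may or may not
        pass the deleteriousness/consequence rules."""
        rng = self.rng
        csq = str(rng.choice(["missense", "synonymous", "stop_gain", "other_exonic", "splicing"]))
        dp = int(rng.integers(8, 41))
        ad_alt = int(rng.integers(max(1, math.ceil(dp * 0.3)), max(2, math.floor(dp * 0.7) + 1)))
        return AnnotatedVariant(
            individual_id=iid,
            chrom=self.gene_chrom[gene],
            pos=self._next_pos(),
            ref="A",
            alt="C",
            gene=gene,
            consequence=csq,
            zygosity="het",
            dp=dp,
            gq=int(rng.integers(15, 100)),
            ad_ref=dp - ad_alt,
            ad_alt=ad_alt,
            splice_distance=int(rng.integers(1, 6)) if csq == "splicing" else None,
            cadd=float(rng.uniform(0, 40)),
            am_class=str(rng.choice(["pathogenic", "benign", "ambiguous"])) if csq == "missense" and rng.random() < 0.5 else None,
            af=_log_uniform(rng, *self.af_range),
            site=_NOMINAL_SITE,
        )


def simulate_sib_genotypes(
    n_snps: int, allele_freqs: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Mendelian-consistent genotypes for one sibling pair.

    Each parent's two haplotypes are drawn per locus from the population
    allele frequency; each sibling inherits one independently chosen
    haplotype from each parent (independent loci). Expected KING-robust
    kinship for the pair is 0.25.
    """
    if np.any((allele_freqs <= 0) | (allele_freqs >= 1)):
        raise ValueError("allele frequencies must lie in (0,1)")
    if n_snps < 100:
        warnings.warn("fewer than 100 SNPs: kinship estimates will be unstable", stacklevel=2)
    mother = rng.random((2, n_snps)) < allele_freqs
    father = rng.random((2, n_snps)) < allele_freqs
    sibs = []
    for _ in range(2):
        from_mother = mother[rng.integers(0, 2, n_snps), np.arange(n_snps)]
        from_father = father[rng.integers(0, 2, n_snps), np.arange(n_snps)]
        sibs.append((from_mother.astype(np.int8) + from_father.astype(np.int8)))
    return sibs[0], sibs[1]


def simulate_phenotypes(
    individuals: Sequence[Individual],
    group_labels: Mapping[str, str],
    effects: Mapping[str, float],
    flip_prob: Mapping[str, float],
    rng: np.random.Generator,
) -> tuple[list[PhenotypeRecord], dict[str, dict[str, float]]]:
    """Draw phenotypes with the configured group effect structure.

    Torque metrics are Gaussian with the case-group means offset from the
    control mean by ``effects[metric]`` within-group standard deviations,
    identically for the solved and unsolved groups. Laterality indexes are
    drawn as a positive magnitude around the task-typical mean with the
    typical sign, flipped with a per-task group-specific probability; the
    atypical count is then computed from the emitted indexes against the
    emitted control means. Age and sex carry no effects.
    """
    unknown = {g for g in group_labels.values()} - {"solved", "unsolved", "control"}
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")

    group_means: dict[str, dict[str, float]] = {}
    draws: dict[str, dict[str, float]] = {iid: {} for iid in group_labels}
    for metric in TORQUE_METRICS:
        eff = effects.get(metric, 0.0) * _TORQUE_SD
        group_means[metric] = {"control": 0.0, "solved": eff, "unsolved": eff}
        for ind in individuals:
            mu = group_means[metric][group_labels[ind.individual_id]]
            draws[ind.individual_id][metric] = float(rng.normal(mu, _TORQUE_SD))
    sinus_eff = effects.get("sinus", 0.0) * _SINUS_SD
    for metric in ("sinus_left", "sinus_right"):
        group_means[metric] = {
            "control": _SINUS_MEAN,
            "solved": _SINUS_MEAN + sinus_eff,
            "unsolved": _SINUS_MEAN + sinus_eff,
        }
        for ind in individuals:
            mu = group_means[metric][group_labels[ind.individual_id]]
            draws[ind.individual_id][metric] = float(max(0.0, rng.normal(mu, _SINUS_SD)))

    for task in LI_TASKS:
        eff = effects.get(task, 0.0) * _LI_SD
        typical = _LI_TYPICAL_MEAN[task]
        group_means[task] = {
            "control": typical,
            "solved": typical + eff,
            "unsolved": typical + eff,
        }
        for ind in individuals:
            label = group_labels[ind.individual_id]
            mu = group_means[task][label]
            magnitude = abs(rng.normal(abs(mu), _LI_SD))
            sign = math.copysign(1.0, mu)
            p = flip_prob["control"] if label == "control" else flip_prob["case"]
            if rng.random() < p:
                sign = -sign
            draws[ind.individual_id][task] = sign * magnitude

    control_ids = [i.individual_id for i in individuals if group_labels[i.individual_id] == "control"]
    control_task_means = {
        task: float(np.mean([draws[cid][task] for cid in control_ids])) for task in LI_TASKS
    }

    records = []
    for ind in individuals:
        d = draws[ind.individual_id]
        rec = PhenotypeRecord(
            individual_id=ind.individual_id,
            li_word=d["li_word"],
            li_praxis=d["li_praxis"],
            li_spatial=d["li_spatial"],
            li_face=d["li_face"],
            frontal_petalia=d["frontal_petalia"],
            frontal_bending=d["frontal_bending"],
            occipital_petalia=d["occipital_petalia"],
            occipital_bending=d["occipital_bending"],
            sinus_left=d["sinus_left"],
            sinus_right=d["sinus_right"],
        )
        n_atyp = count_atypical(rec, control_task_means)
        records.append(
            PhenotypeRecord(**{**rec.__dict__, "n_atypical": n_atyp})
        )
    return records, group_means


def _make_individuals(config: SimConfig, rng: np.random.Generator) -> list[Individual]:
    inds = []
    n_stage1_cases = min(15, config.n_cases)
    n_stage1_controls = min(15, config.n_controls)
    for cohort, n, n_stage1 in (
        ("case", config.n_cases, n_stage1_cases),
        ("control", config.n_controls, n_stage1_controls),
    ):
        for k in range(n):
            prefix = "SIM" if cohort == "case" else "CON"
            hand = rng.random()
            inds.append(
                Individual(
                    individual_id=f"{prefix}{k + 1:03d}",
                    cohort=cohort,
                    stage="I" if k < n_stage1 else "II",
                    sex="M" if rng.random() < 0.45 else "F",
                    age=float(np.clip(rng.normal(41, 17), 18, 90)),
                    pcd=False,
                    handedness="left" if hand < 0.22 else ("ambidextrous" if hand < 0.25 else "right"),
                )
            )
    return inds


def simulate_cohort(config: SimConfig | None = None) -> SimulatedCohort:
    """Generate the complete synthetic study for one seed."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)

    counts = config.model_counts()
    n_candidates = config.n_candidate_genes
    n_rec = max(counts["recessive_hom"] + counts["compound_het"], 1)
    n_x = max(counts["x_linked"], 1)
    n_dom = max(counts["dominant"], 1)
    n_unconfirmed = max(n_candidates - n_rec - n_x - n_dom, 2)
    if n_rec + n_x + n_dom > n_candidates:
        raise ValueError(
            "infeasible config: more planted cases than candidate genes "
            f"({n_rec + n_x + n_dom} needed, {n_candidates} available)"
        )
    if counts["compound_het"] > config.background_gene_pool:
        raise ValueError("infeasible config: more compound-het cases than the gene pool")

    autosomes = [str(c) for c in range(1, 23)]
    candidates: list[CandidateGene] = []
    gene_chrom: dict[str, str] = {}
    rec_genes = [f"CREC{i:03d}" for i in range(n_rec)]
    x_genes = [f"CXLK{i:03d}" for i in range(n_x)]
    dom_genes = [f"CDOM{i:03d}" for i in range(n_dom)]
    unc_genes = [f"CUNC{i:03d}" for i in range(n_unconfirmed)]
    for g in rec_genes:
        gene_chrom[g] = str(rng.choice(autosomes))
        candidates.append(CandidateGene(g, "synthetic panel", "recessive", pcd_linked=bool(rng.random() < 0.6)))
    for g in x_genes:
        gene_chrom[g] = "X"
        candidates.append(CandidateGene(g, "synthetic panel", "x_linked", pcd_linked=False))
    for g in dom_genes:
        gene_chrom[g] = str(rng.choice(autosomes))
        candidates.append(CandidateGene(g, "synthetic panel", "dominant", pcd_linked=False))
    for g in unc_genes:
        gene_chrom[g] = str(rng.choice(autosomes))
        candidates.append(CandidateGene(g, "synthetic panel", "unconfirmed", pcd_linked=False))
    bg_genes = [f"BG{i:04d}" for i in range(config.background_gene_pool)]
    for g in bg_genes:
        gene_chrom[g] = str(rng.choice(autosomes))

    individuals = _make_individuals(config, rng)
    cases = [i for i in individuals if i.cohort == "case"]
    controls = [i for i in individuals if i.cohort == "control"]

    # X-linked planted cases must be male: force sex where needed.
    solved_idx = list(rng.choice(len(cases), size=config.n_solved_target, replace=False))
    model_for_case: dict[str, str] = {}
    queue = (
        ["recessive_hom"] * counts["recessive_hom"]
        + ["compound_het"] * counts["compound_het"]
        + ["x_linked"] * counts["x_linked"]
        + ["dominant"] * counts["dominant"]
    )
    for idx, model in zip(solved_idx, queue):
        ind = cases[idx]
        if model == "x_linked" and ind.sex != "M":
            ind = Individual(ind.individual_id, ind.cohort, ind.stage, "M", ind.age,
                             ind.pcd, ind.handedness)
            cases[idx] = ind
            for j, other in enumerate(individuals):
                if other.individual_id == ind.individual_id:
                    individuals[j] = ind
                    break
        model_for_case[ind.individual_id] = model

    factory = _VariantFactory(rng, gene_chrom, config.rare_af_range)
    variants: dict[str, list[AnnotatedVariant]] = {i.individual_id: [] for i in individuals}
    solved_truth: dict[str, tuple[str, str]] = {}

    rec_pool = list(rec_genes)
    x_pool = list(x_genes)
    dom_pool = list(dom_genes)
    for iid, model in model_for_case.items():
        if model == "recessive_hom":
            gene = rec_pool.pop() if rec_pool else str(rng.choice(rec_genes))
            variants[iid].append(factory.causal(iid, gene, "hom", max_af=0.005))
            solved_truth[iid] = (gene, "recessive")
        elif model == "compound_het":
            gene = rec_pool.pop() if rec_pool else str(rng.choice(rec_genes))
            cis = config.chet_phase_cis
            variants[iid].append(factory.causal(iid, gene, "het", 0.005, phased_cis=cis))
            variants[iid].append(factory.causal(iid, gene, "het", 0.005, phased_cis=cis))
            solved_truth[iid] = (gene, "recessive")
        elif model == "x_linked":
            gene = x_pool.pop() if x_pool else str(rng.choice(x_genes))
            variants[iid].append(factory.causal(iid, gene, "hemi", max_af=0.005))
            solved_truth[iid] = (gene, "x_linked")
        else:
            gene = dom_pool.pop() if dom_pool else str(rng.choice(dom_genes))
            variants[iid].append(factory.causal(iid, gene, "het", max_af=0.00005))
            solved_truth[iid] = (gene, "dominant")

    # Background singles in non-candidate genes for everyone.
    for ind in individuals:
        for _ in range(rng.poisson(config.mean_background_variants)):
            gene = str(rng.choice(bg_genes))
            variants[ind.individual_id].append(factory.background(ind.individual_id, gene))

    # Shared qualifying chet genes in a case and a control, to exercise
    # control subtraction (non-candidate genes: cannot change solved status).
    unsolved_cases = [i for i in cases if i.individual_id not in solved_truth]
    for k in range(config.n_shared_chet_genes):
        gene = bg_genes[k]
        case = cases[int(rng.integers(0, len(cases)))]
        control = controls[int(rng.integers(0, len(controls)))]
        for iid in (case.individual_id, control.individual_id):
            variants[iid].append(factory.causal(iid, gene, "het", 0.005))
            variants[iid].append(factory.causal(iid, gene, "het", 0.005))

    # Unconfirmed-candidate chet configurations in unsolved cases, to
    # exercise "notable, not solved".
    for k in range(min(config.n_notable_cases, len(unsolved_cases), len(unc_genes))):
        iid = unsolved_cases[k].individual_id
        gene = unc_genes[k]
        variants[iid].append(factory.causal(iid, gene, "het", 0.005))
        variants[iid].append(factory.causal(iid, gene, "het", 0.005))

    # Kinship genotype matrix with planted sibling pairs among the cases.
    freqs = rng.uniform(0.05, 0.5, config.n_kinship_snps)
    sample_ids = [i.individual_id for i in individuals]
    geno = rng.binomial(2, freqs, size=(len(sample_ids), config.n_kinship_snps)).astype(float)
    sib_pairs: list[tuple[str, str]] = []
    for k in range(config.n_sib_pairs):
        a, b = 2 * k, 2 * k + 1
        if b >= len(cases):
            break
        s1, s2 = simulate_sib_genotypes(config.n_kinship_snps, freqs, rng)
        geno[a] = s1
        geno[b] = s2
        sib_pairs.append((cases[a].individual_id, cases[b].individual_id))
    snp_ids = [f"snp{j:05d}" for j in range(config.n_kinship_snps)]
    genotype_matrix = pd.DataFrame(geno, index=sample_ids, columns=snp_ids)
    variant_freqs = pd.Series(freqs, index=snp_ids, name="af")

    group_labels = {
        i.individual_id: (
            "control"
            if i.cohort == "control"
            else ("solved" if i.individual_id in solved_truth else "unsolved")
        )
        for i in individuals
    }
    phenotypes, group_means = simulate_phenotypes(
        individuals, group_labels, config.phenotype_effects, config.atypical_flip_prob, rng
    )

    truth = GroundTruth(
        solved=solved_truth,
        group_labels=group_labels,
        sib_pairs=tuple(sib_pairs),
        group_means=group_means,
    )
    return SimulatedCohort(
        individuals=individuals,
        variants=variants,
        candidates=candidates,
        genotype_matrix=genotype_matrix,
        variant_freqs=variant_freqs,
        phenotypes=phenotypes,
        ground_truth=truth,
    )
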