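"""Gene-level inheritance models and solved-status assignment.

Per individual, retained variants are aggregated per gene into a genotype
configuration. Under the recessive/X-linked model a gene qualifies with a
homozygous variant, two heterozygous variants not known to be in phase
(potential compound heterozygote), or — in males — any variant on
chromosome X. Under the dominant model one retained variant (at the far
stricter allele-frequency cutoff) suffices.

Genes qualifying in controls by the same criteria are subtracted from the
case sets (recessive: present in any control; dominant: present in more
than one control), removing genes burdened with many rare variants in the
population or prone to recurrent pipeline artifacts.

Surviving qualifying genes are matched against the candidate list: a case
is "solved" when a candidate gene with a confirmed matching inheritance
mode qualifies, the recessive/X-linked model taking precedence over the
dominant model. Qualifying candidate genes whose causal role is
unconfirmed are recorded as notable, with the case left unsolved.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import AnnotatedVariant, CandidateGene, Individual, X_CHROMS
from .variant_filters import retained_variants

__all__ = [
    "GeneEvidence",
    "SolvedCall",
    "collect_gene_evidence",
    "qualify_recessive",
    "qualify_dominant",
    "qualifying_genes",
    "subtract_control_genes",
    "assign_solved",
    "summarize_calls",
    "run_prioritization",
]


@dataclass(frozen=True)
class GeneEvidence:
    """Variant support for one gene in one individual, with its genotype
    configuration and per-model qualification."""

    individual_id: str
    gene: str
    variants: tuple[AnnotatedVariant, ...]
    config: str  # hom | chet_unphased | chet_phased_cis | x_hemi | single_het
    qualifies_recessive: bool
    qualifies_dominant: bool

    @property
    def max_cadd(self) -> float:
        scores = [v.cadd for v in self.variants if v.cadd is not None]
        return max(scores) if scores else float("-inf")

    @property
    def model(self) -> str:
        """Inheritance model implied by the configuration."""
        return "x_linked" if self.config == "x_hemi" else "recessive"


@dataclass(frozen=True)
class SolvedCall:
    individual_id: str
    status: str  # solved | unsolved
    assigned_gene: str | None = None
    model: str | None = None  # recessive | x_linked | dominant
    notable_genes: tuple[str, ...] = ()
    tie_flag: bool = False

    def __post_init__(self) -> None:
        if self.status not in {"solved", "unsolved"}:
            raise ValueError(f"bad status {self.status!r}")
        if (self.status == "solved") != (self.assigned_gene is not None):
            raise ValueError("solved status requires an assigned gene and vice versa")


def _config(variants: Sequence[AnnotatedVariant], sex: str) -> str:
    hets = [v for v in variants if v.zygosity == "het"]
    if any(v.zygosity == "hom" for v in variants):
        return "hom"
    if len(hets) >= 2:
        return "chet_phased_cis" if any(v.phased_cis for v in hets) else "chet_unphased"
    if sex == "M" and variants and all(v.chrom in X_CHROMS for v in variants):
        return "x_hemi"
    return "single_het"


def collect_gene_evidence(
    variants: Iterable[AnnotatedVariant], sex: str
) -> list[GeneEvidence]:
    """Aggregate one individual's retained variants into per-gene evidence."""
    by_gene: dict[str, list[AnnotatedVariant]] = {}
    iid = None
    for v in variants:
        if iid is None:
            iid = v.individual_id
        elif v.individual_id != iid:
            raise ValueError("variants from more than one individual")
        by_gene.setdefault(v.gene, []).append(v)
    out = []
    for gene in sorted(by_gene):
        vs = tuple(by_gene[gene])
        config = _config(vs, sex)
        out.append(
            GeneEvidence(
                individual_id=iid,  # type: ignore[arg-type]
                gene=gene,
                variants=vs,
                config=config,
                qualifies_recessive=config in {"hom", "chet_unphased", "x_hemi"},
                qualifies_dominant=len(vs) >= 1,
            )
        )
    return out


def qualify_recessive(e: GeneEvidence) -> bool:
    """Biallelic (hom or unphased compound het) or male X hemizygous."""
    return e.config in {"hom", "chet_unphased", "x_hemi"}


def qualify_dominant(e: GeneEvidence) -> bool:
    """At least one retained variant, in any zygosity."""
    return len(e.variants) >= 1


def qualifying_genes(evidence: Iterable[GeneEvidence], model: str) -> set[str]:
    if model == "recessive":
        return {e.gene for e in evidence if qualify_recessive(e)}
    if model == "dominant":
        return {e.gene for e in evidence if qualify_dominant(e)}
    raise ValueError(f"unknown model {model!r}")


def subtract_control_genes(
    case_gene_sets: Mapping[str, set[str]],
    control_gene_sets: Mapping[str, set[str]],
    model: str,
) -> dict[str, set[str]]:
    """Drop genes qualifying in controls from every case's qualifying set.

    Recessive: a single qualifying control suffices to drop the gene;
    dominant: the gene must qualify in more than one control.
    """
    counts: Counter[str] = Counter()
    for genes in control_gene_sets.values():
        counts.update(genes)
    threshold = 1 if model == "recessive" else 2
    dropped = {g for g, n in counts.items() if n >= threshold}
    return {iid: genes - dropped for iid, genes in case_gene_sets.items()}


def assign_solved(
    individual: Individual,
    qualifying_by_model: Mapping[str, Iterable[str]],
    candidates: Sequence[CandidateGene],
    evidence_by_gene: Mapping[str, GeneEvidence] | None = None,
) -> SolvedCall:
    """Match control-subtracted qualifying genes against the candidate list.

    The recessive/X-linked model is evaluated first; the dominant model is
    consulted only for individuals it leaves unsolved. A tie between two or
    more confirmed candidate genes under one model is broken by the highest
    supporting CADD score, then lexicographically, and flagged.
    """
    by_symbol = {c.gene: c for c in candidates}
    evidence_by_gene = evidence_by_gene or {}
    notable: list[str] = []

    def try_model(model: str) -> tuple[str | None, str | None, bool]:
        matches: list[str] = []
        for gene in sorted(set(qualifying_by_model.get(model, ()))):
            cand = by_symbol.get(gene)
            if cand is None:
                continue
            if cand.confirmed_mode == "unconfirmed":
                if gene not in notable:
                    notable.append(gene)
                continue
            ev = evidence_by_gene.get(gene)
            gene_model = ev.model if (ev is not None and model == "recessive") else model
            if cand.confirmed_mode == gene_model:
                matches.append(gene)
        if not matches:
            return None, None, False
        tie = len(matches) > 1
        if tie:
            matches.sort(
                key=lambda g: (
                    -(evidence_by_gene[g].max_cadd if g in evidence_by_gene else float("-inf")),
                    g,
                )
            )
        winner = matches[0]
        winner_mode = by_symbol[winner].confirmed_mode
        return winner, winner_mode, tie

    gene, model, tie = try_model("recessive")
    if gene is None:
        gene, model, tie = try_model("dominant")
    if gene is None:
        return SolvedCall(
            individual_id=individual.individual_id,
            status="unsolved",
            notable_genes=tuple(notable),
        )
    return SolvedCall(
        individual_id=individual.individual_id,
        status="solved",
        assigned_gene=gene,
        model=model,
        notable_genes=tuple(notable),
        tie_flag=tie,
    )


def summarize_calls(
    calls: Sequence[SolvedCall],
    individuals: Sequence[Individual],
    candidates: Sequence[CandidateGene] = (),
    n_controls_flagged: int = 0,
) -> dict:
    """Group counts over the per-individual calls (cases only), plus the
    number of controls meeting the case-defining criteria."""
    by_id = {i.individual_id: i for i in individuals}
    by_symbol = {c.gene: c for c in candidates}
    cases = [c for c in calls if by_id[c.individual_id].cohort == "case"]
    solved = [c for c in cases if c.status == "solved"]

    def _pcd_linked(call: SolvedCall) -> bool:
        cand = by_symbol.get(call.assigned_gene or "")
        return cand.pcd_linked if cand else False

    summary = {
        "n_cases": len(cases),
        "n_controls": sum(1 for i in individuals if i.cohort == "control"),
        "n_solved": len(solved),
        "n_unsolved": len(cases) - len(solved),
        "n_controls_flagged": n_controls_flagged,
        "n_solved_by_model": dict(Counter(c.model for c in solved)),
        "n_solved_by_stage": dict(Counter(by_id[c.individual_id].stage for c in solved)),
        "n_solved_stage_by_model": dict(
            Counter(f"{by_id[c.individual_id].stage}:{c.model}" for c in solved)
        ),
        "n_solved_pcd": sum(1 for c in solved if by_id[c.individual_id].pcd),
        "n_solved_nonpcd_pcd_linked_gene": sum(
            1
            for c in solved
            if not by_id[c.individual_id].pcd
            and c.model in {"recessive", "x_linked"}
            and _pcd_linked(c)
        ),
        "n_solved_nonpcd_laterality_gene": sum(
            1
            for c in solved
            if not by_id[c.individual_id].pcd
            and c.model in {"recessive", "x_linked"}
            and not _pcd_linked(c)
        ),
    }
    return summary


def run_prioritization(
    variants_by_individual: Mapping[str, Sequence[AnnotatedVariant]],
    individuals: Sequence[Individual],
    candidates: Sequence[CandidateGene],
    control_scope: str = "pooled",
) -> tuple[list[SolvedCall], dict, dict]:
    """The full prioritization pipeline on an annotated cohort.

    Returns (per-case calls, summary counts, per-individual recessive
    evidence by gene). Controls are scored with the identical criteria;
    a control is flagged when a qualifying recessive/X-linked gene matches
    the candidate list (any confirmation status).

    ``control_scope`` selects which controls enter the dominant-model
    subtraction: the pooled control cohort (default) or stage II only.
    """
    if control_scope not in {"pooled", "stage_II"}:
        raise ValueError(f"bad control_scope {control_scope!r}")
    by_id = {i.individual_id: i for i in individuals}
    cases = [i for i in individuals if i.cohort == "case"]
    controls = [i for i in individuals if i.cohort == "control"]
    candidate_symbols = {c.gene for c in candidates}

    evidence: dict[str, dict[str, dict[str, GeneEvidence]]] = {"recessive": {}, "dominant": {}}
    qual: dict[str, dict[str, set[str]]] = {"recessive": {}, "dominant": {}}
    for ind in individuals:
        vs = variants_by_individual.get(ind.individual_id, ())
        for model in ("recessive", "dominant"):
            retained = retained_variants(vs, model)
            evs = collect_gene_evidence(retained, ind.sex) if retained else []
            evidence[model][ind.individual_id] = {e.gene: e for e in evs}
            qual[model][ind.individual_id] = qualifying_genes(evs, model)

    control_ids = [c.individual_id for c in controls]
    dom_control_ids = (
        control_ids
        if control_scope == "pooled"
        else [c.individual_id for c in controls if c.stage == "II"]
    )
    case_qual = {
        "recessive": subtract_control_genes(
            {i.individual_id: qual["recessive"][i.individual_id] for i in cases},
            {cid: qual["recessive"][cid] for cid in control_ids},
            "recessive",
        ),
        "dominant": subtract_control_genes(
            {i.individual_id: qual["dominant"][i.individual_id] for i in cases},
            {cid: qual["dominant"][cid] for cid in dom_control_ids},
            "dominant",
        ),
    }

    calls = []
    for ind in cases:
        ev = dict(evidence["dominant"][ind.individual_id])
        ev.update(evidence["recessive"][ind.individual_id])
        calls.append(
            assign_solved(
                ind,
                {
                    "recessive": case_qual["recessive"][ind.individual_id],
                    "dominant": case_qual["dominant"][ind.individual_id],
                },
                candidates,
                evidence_by_gene=ev,
            )
        )

    flagged = [
        cid
        for cid in control_ids
        if qual["recessive"][cid] & candidate_symbols
    ]
    summary = summarize_calls(calls, individuals, candidates, n_controls_flagged=len(flagged))
    summary["flagged_controls"] = sorted(flagged)
    return calls, summary, evidence["recessive"]
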