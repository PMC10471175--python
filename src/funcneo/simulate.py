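"""Synthetic data with planted ground truth.

Real inputs to this pipeline are tumor/normal exome variant calls with tumor
RNA read support, a reference proteome, and ELISPOT plate counts.  None of
those are needed to exercise the pipeline: this module generates all three
with a known planted truth — per-variant tier membership in the expression
cascade, and per-mutation immunogenicity with its responding T cell subset —
so recovery can be checked exactly.

Defaults emulate the structure of the screen the pipeline implements: a
4,771-variant somatic call set narrowing to 1,481 coding, 270 RNA-expressed
and 39 strictly expressed mutations; 16 screening pools; 3 replicate ELISPOT
wells per condition; background wells at a Poisson rate of 10 SFC and
immunogenic wells at 15x background; and 4 immunogenic mutations of which 3
are recognized by CD4+ T cells only and 1 by both subsets.

Every generator is a pure function of (config, seed): a fixed seed gives
byte-identical output.  Each generator draws from its own named substream of
the global seed, so regenerating one artifact never perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .elispot import ElispotCondition
from .peptides import (
    AMINO_ACIDS,
    PeptideCandidate,
    ProteinRecord,
    apply_missense,
    design_long_peptides,
    peptides_to_frame,
    write_peptide_manifest,
    write_peptides_fasta,
    write_proteome_fasta,
)
from .pools import PeptidePool, assign_pools, pools_to_frame
from .variants import SomaticVariant, write_variant_table

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "Fixture",
    "gen_proteome",
    "gen_variant_table",
    "gen_elispot_plate",
    "end_to_end_fixture",
]


class SimulationError(ValueError):
    """Infeasible or invalid simulation configuration."""


# Named substreams of the global seed, one per generator.
_STREAMS = {"proteome": 0, "variants": 1, "immunogenic": 2, "plate_pool": 3, "plate_single": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic screen.

    ``tier_counts`` are the planted cascade sizes (total, coding, expressed,
    strict).  ``lambda_background`` is the control-well Poisson SFC rate and
    ``effect_multiplier`` scales it for wells stimulated with an immunogenic
    peptide.  ``immunogenic_labels`` gives the responding-subset truth for
    each planted immunogenic mutation.
    """

    seed: int = 0
    tier_counts: tuple = (4771, 1481, 270, 39)
    rna_depth_range: tuple = (60, 300)
    n_proteins: int = 45
    protein_length_range: tuple = (80, 200)
    lambda_background: float = 10.0
    effect_multiplier: float = 15.0
    n_replicates: int = 3
    n_immunogenic: int = 4
    immunogenic_labels: tuple = ("CD4_only", "CD4_only", "CD4_only", "dual")
    n_pools: int = 16
    anchors: tuple = (6, 15)
    peptide_length: int = 20
    overdispersion: Optional[float] = None  # negative-binomial dispersion; None = pure Poisson

    def __post_init__(self) -> None:
        t = self.tier_counts
        if len(t) != 4 or not (t[0] >= t[1] >= t[2] >= t[3] >= 0):
            raise SimulationError(f"tier_counts must be 4 non-increasing counts, got {t}")
        if self.lambda_background <= 0:
            raise SimulationError("lambda_background must be positive")
        if self.effect_multiplier < 1:
            raise SimulationError("effect_multiplier must be >= 1")
        if self.n_replicates < 2:
            raise SimulationError("n_replicates must be >= 2")
        if self.n_proteins < 1:
            raise SimulationError("n_proteins must be >= 1")
        lo, hi = self.protein_length_range
        if not (1 <= lo <= hi):
            raise SimulationError(f"degenerate protein_length_range {self.protein_length_range}")
        dlo, dhi = self.rna_depth_range
        if not (0 <= dlo <= dhi) or dhi < 50:
            raise SimulationError(
                f"rna_depth_range {self.rna_depth_range} must be a valid interval with max >= 50"
            )
        if self.n_immunogenic > t[3]:
            raise SimulationError("n_immunogenic cannot exceed the strict-tier count")
        if len(self.immunogenic_labels) != self.n_immunogenic:
            raise SimulationError("immunogenic_labels must have one label per immunogenic mutation")
        for lab in self.immunogenic_labels:
            if lab not in ("CD4_only", "CD8_only", "dual"):
                raise SimulationError(f"unknown subset label {lab!r}")


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated screen."""

    tier_of_variant: dict = field(default_factory=dict)  # variant_id -> tier name
    strict_mutations: dict = field(default_factory=dict)  # mutation_id -> metadata dict
    immunogenic: dict = field(default_factory=dict)  # mutation_id -> subset label
    immunogenic_peptides: dict = field(default_factory=dict)  # peptide_id -> subset label

    def tier_counts(self) -> tuple[int, int, int, int]:
        tiers = list(self.tier_of_variant.values())
        n_total = len(tiers)
        n_coding = sum(t != "noncoding" for t in tiers)
        n_expressed = sum(t in ("expressed", "strict") for t in tiers)
        n_strict = sum(t == "strict" for t in tiers)
        return (n_total, n_coding, n_expressed, n_strict)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "tier_of_variant": self.tier_of_variant,
                    "strict_mutations": self.strict_mutations,
                    "immunogenic": self.immunogenic,
                    "immunogenic_peptides": self.immunogenic_peptides,
                },
                indent=2,
            )
        )


def gen_proteome(config: SimulationConfig) -> list[ProteinRecord]:
    """Uniform-random toy proteome (one record per protein/isoform)."""
    rng = _rng(config.seed, "proteome")
    lo, hi = config.protein_length_range
    out = []
    aa = np.array(list(AMINO_ACIDS))
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(aa[rng.integers(0, 20, size=length)])
        out.append(
            ProteinRecord(
                protein_id=f"prot{i + 1:03d}",
                sequence=seq,
                gene_symbol=f"GENE{i + 1:03d}",
                isoform_label="iso1",
            )
        )
    return out


def _random_alt_residue(rng: np.random.Generator, ref: str) -> str:
    choices = [a for a in AMINO_ACIDS if a != ref]
    return choices[int(rng.integers(0, len(choices)))]


def gen_variant_table(
    config: SimulationConfig, proteome: Sequence[ProteinRecord]
) -> tuple[list[SomaticVariant], SyntheticTruth]:
    """Variant table with planted cascade-tier membership.

    Exactly ``tier_counts[i]`` variants satisfy each tier under the default
    thresholds (in both read-count modes): strict-tier variants get RNA VAF
    in [0.24, 0.8] with >= 10 variant reads at >= 50x depth; expressed-but-
    not-strict variants get 1–9 variant reads at depth keeping VAF < 0.20;
    coding-but-unexpressed variants get zero variant RNA reads.
    """
    n_total, n_coding, n_expressed, n_strict = config.tier_counts
    if n_strict > 0 and not proteome:
        raise SimulationError("strict-tier variants require a non-empty proteome")
    rng = _rng(config.seed, "variants")
    dlo, dhi = config.rna_depth_range
    truth = SyntheticTruth()
    variants: list[SomaticVariant] = []

    def dna_counts() -> tuple[int, int]:
        depth = int(rng.integers(60, 160))
        alt = int(rng.binomial(depth, 0.3))
        return alt, depth - alt

    def base_fields(i: int) -> dict:
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        return {
            "variant_id": f"var{i + 1:05d}",
            "chromosome": str(int(rng.integers(1, 20))),
            "position": int(rng.integers(1, 10_000_000)),
            "ref_allele": str(ref),
            "alt_allele": str(alt),
        }

    idx = 0
    # --- strict tier: well-expressed missense mutations -------------------
    for j in range(n_strict):
        prot = proteome[j % len(proteome)]
        pos = int(rng.integers(1, len(prot) + 1))
        aa_ref = prot.sequence[pos - 1]
        aa_alt = _random_alt_residue(rng, aa_ref)
        depth = int(rng.integers(max(50, dlo), max(dhi, 51) + 1))
        vaf = float(rng.uniform(0.25, 0.75))
        alt_reads = min(depth, max(10, int(round(vaf * depth))))
        dna_alt, dna_ref = dna_counts()
        mutation_id = f"{j + 1:02d}"
        fields = base_fields(idx)
        variants.append(
            SomaticVariant(
                **fields,
                variant_class="missense",
                gene_symbol=prot.gene_symbol,
                transcript_id=prot.protein_id,
                protein_position=pos,
                aa_ref=aa_ref,
                aa_alt=aa_alt,
                dna_alt_reads=dna_alt,
                dna_ref_reads=dna_ref,
                rna_alt_reads=alt_reads,
                rna_depth=depth,
            )
        )
        truth.tier_of_variant[fields["variant_id"]] = "strict"
        truth.strict_mutations[mutation_id] = {
            "variant_id": fields["variant_id"],
            "protein_id": prot.protein_id,
            "gene": prot.gene_symbol,
            "protein_position": pos,
            "aa_ref": aa_ref,
            "aa_alt": aa_alt,
        }
        idx += 1

    # --- expressed but below the strict thresholds ------------------------
    for _ in range(n_expressed - n_strict):
        alt_reads = int(rng.integers(1, 10))  # < 10 variant reads
        depth = int(rng.integers(max(5 * alt_reads + 1, dlo), max(dhi, 5 * alt_reads + 2) + 1))
        klass = str(rng.choice(["missense", "synonymous", "splice_region"]))
        prot = proteome[int(rng.integers(0, len(proteome)))] if proteome else None
        kw: dict = {}
        if klass == "missense" and prot is not None:
            pos = int(rng.integers(1, len(prot) + 1))
            aa_ref = prot.sequence[pos - 1]
            kw = {
                "gene_symbol": prot.gene_symbol,
                "transcript_id": prot.protein_id,
                "protein_position": pos,
                "aa_ref": aa_ref,
                "aa_alt": _random_alt_residue(rng, aa_ref),
            }
        elif klass == "synonymous" and prot is not None:
            kw = {
                "gene_symbol": prot.gene_symbol,
                "transcript_id": prot.protein_id,
                "protein_position": int(rng.integers(1, len(prot) + 1)),
            }
        dna_alt, dna_ref = dna_counts()
        fields = base_fields(idx)
        variants.append(
            SomaticVariant(
                **fields,
                variant_class=klass,
                dna_alt_reads=dna_alt,
                dna_ref_reads=dna_ref,
                rna_alt_reads=alt_reads,
                rna_depth=depth,
                **kw,
            )
        )
        truth.tier_of_variant[fields["variant_id"]] = "expressed"
        idx += 1

    # --- coding but with no variant-supporting RNA reads ------------------
    for _ in range(n_coding - n_expressed):
        klass = str(rng.choice(["missense", "synonymous", "splice_region"]))
        prot = proteome[int(rng.integers(0, len(proteome)))] if proteome else None
        kw = {}
        if klass == "missense" and prot is not None:
            pos = int(rng.integers(1, len(prot) + 1))
            aa_ref = prot.sequence[pos - 1]
            kw = {
                "gene_symbol": prot.gene_symbol,
                "transcript_id": prot.protein_id,
                "protein_position": pos,
                "aa_ref": aa_ref,
                "aa_alt": _random_alt_residue(rng, aa_ref),
            }
        dna_alt, dna_ref = dna_counts()
        fields = base_fields(idx)
        variants.append(
            SomaticVariant(
                **fields,
                variant_class=klass,
                dna_alt_reads=dna_alt,
                dna_ref_reads=dna_ref,
                rna_alt_reads=0,
                rna_depth=int(rng.integers(0, dhi + 1)),
                **kw,
            )
        )
        truth.tier_of_variant[fields["variant_id"]] = "coding"
        idx += 1

    # --- noncoding remainder ----------------------------------------------
    for _ in range(n_total - n_coding):
        dna_alt, dna_ref = dna_counts()
        depth = int(rng.integers(0, dhi + 1))
        fields = base_fields(idx)
        variants.append(
            SomaticVariant(
                **fields,
                variant_class="noncoding",
                dna_alt_reads=dna_alt,
                dna_ref_reads=dna_ref,
                rna_alt_reads=int(rng.integers(0, depth + 1)),
                rna_depth=depth,
            )
        )
        truth.tier_of_variant[fields["variant_id"]] = "noncoding"
        idx += 1

    # interleave tiers so filter order, not input order, drives the counts
    order = rng.permutation(len(variants))
    variants = [variants[i] for i in order]
    return variants, truth


def _draw_counts(
    rng: np.random.Generator, rate: float, n: int, overdispersion: Optional[float]
) -> tuple:
    if overdispersion is None:
        return tuple(int(x) for x in rng.poisson(rate, size=n))
    # negative binomial parameterized by mean `rate` and dispersion k
    k = overdispersion
    p = k / (k + rate)
    return tuple(int(x) for x in rng.negative_binomial(k, p, size=n))


def gen_elispot_plate(
    config: SimulationConfig,
    stimulus_ids: Sequence[str],
    immunogenic_ids: Sequence[str] = (),
    arm: str = "bulk",
    control_id: str = "control",
    rng: Optional[np.random.Generator] = None,
    stream: str = "plate_pool",
) -> list[ElispotCondition]:
    """Replicate SFC counts for one plate arm.

    Control and non-immunogenic stimulus wells draw from
    Poisson(lambda_background); stimuli in ``immunogenic_ids`` draw from
    Poisson(effect_multiplier x lambda_background).
    """
    if rng is None:
        rng = _rng(config.seed, stream)
    immunogenic = set(immunogenic_ids)
    lam = config.lambda_background
    hot = config.effect_multiplier * lam
    conditions = [
        ElispotCondition(
            stimulus_id=control_id,
            arm=arm,
            replicate_counts=_draw_counts(rng, lam, config.n_replicates, config.overdispersion),
        )
    ]
    for sid in stimulus_ids:
        rate = hot if sid in immunogenic else lam
        conditions.append(
            ElispotCondition(
                stimulus_id=sid,
                arm=arm,
                replicate_counts=_draw_counts(rng, rate, config.n_replicates, config.overdispersion),
            )
        )
    return conditions


def _arm_recognizes(label: str, arm: str) -> bool:
    if arm == "bulk":
        return True
    if arm == "CD4":
        return label in ("CD4_only", "dual")
    if arm == "CD8":
        return label in ("CD8_only", "dual")
    raise SimulationError(f"unknown arm {arm!r}")


@dataclass
class Fixture:
    """A complete synthetic screen: inputs, intermediates, and planted truth."""

    config: SimulationConfig
    proteome: list
    variants: list
    truth: SyntheticTruth
    peptides: list  # all designed PeptideCandidate (mutant + WT)
    pooled_peptide_ids: list  # the mutant candidates that enter pools
    pools: list
    plate_pool: list  # bulk-arm pool-stage conditions
    plates_single: dict  # arm -> singleton-stage conditions

    @property
    def manifest(self):
        gene_by_mut = {m: meta["gene"] for m, meta in self.truth.strict_mutations.items()}
        return peptides_to_frame(self.peptides, gene_by_mut)

    def expected_hits(self) -> dict:
        """mutation_id -> (subset label, set of its mutant peptide ids)."""
        out = {}
        for mut, label in self.truth.immunogenic.items():
            pids = {
                p.peptide_id for p in self.peptides if p.mutation_id == mut and p.is_mutant
            }
            out[mut] = (label, pids)
        return out

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .elispot import write_plate
        from .pools import write_pool_manifest

        write_proteome_fasta(self.proteome, out / "proteome.fasta")
        write_variant_table(self.variants, out / "variants.tsv")
        gene_by_mut = {m: meta["gene"] for m, meta in self.truth.strict_mutations.items()}
        write_peptide_manifest(self.peptides, out / "peptides.tsv", gene_by_mut)
        write_peptides_fasta(self.peptides, out / "peptides.fasta")
        write_pool_manifest(self.pools, out / "pools.tsv")
        write_plate(self.plate_pool, out / "plate_pool.tsv")
        for arm, conds in self.plates_single.items():
            write_plate(conds, out / f"plate_single_{arm}.tsv")
        self.truth.to_json(out / "truth.json")


def end_to_end_fixture(config: SimulationConfig) -> Fixture:
    """Build a full synthetic screen with planted truth.

    Filters the generated variant table, designs mutant/WT long-peptide pairs
    for the strict-tier missense mutations, pools the mutant candidates, and
    simulates both screening stages (pool stage in the bulk arm; singleton
    stage in bulk, CD4, and CD8 arms).
    """
    proteome = gen_proteome(config)
    by_id = {p.protein_id: p for p in proteome}
    variants, truth = gen_variant_table(config, proteome)

    # design peptides for the planted strict mutations
    peptides: list[PeptideCandidate] = []
    for mut_id in sorted(truth.strict_mutations):
        meta = truth.strict_mutations[mut_id]
        ref = by_id[meta["protein_id"]]
        mutant = apply_missense(ref, meta["protein_position"], meta["aa_ref"], meta["aa_alt"])
        peptides.extend(
            design_long_peptides(
                mutant, ref, meta["protein_position"],
                anchors=config.anchors, length=config.peptide_length, mutation_id=mut_id,
            )
        )

    pooled_ids = [p.peptide_id for p in peptides if p.is_mutant]
    pools = assign_pools(pooled_ids, config.n_pools, ordering_seed=config.seed)

    # plant immunogenicity on n_immunogenic strict mutations
    rng_imm = _rng(config.seed, "immunogenic")
    mut_ids = sorted(truth.strict_mutations)
    chosen = rng_imm.choice(len(mut_ids), size=config.n_immunogenic, replace=False)
    for pick, label in zip(sorted(int(c) for c in chosen), config.immunogenic_labels):
        truth.immunogenic[mut_ids[pick]] = label
    for p in peptides:
        if p.is_mutant and p.mutation_id in truth.immunogenic:
            truth.immunogenic_peptides[p.peptide_id] = truth.immunogenic[p.mutation_id]

    mutation_of = {p.peptide_id: p.mutation_id for p in peptides}

    # pool stage: a pool is hot iff it contains an immunogenic peptide
    hot_pools = [
        pool.pool_id
        for pool in pools
        if any(mutation_of[pid] in truth.immunogenic for pid in pool.member_peptide_ids)
    ]
    rng_pool = _rng(config.seed, "plate_pool")
    plate_pool = gen_elispot_plate(
        config, [p.pool_id for p in pools], hot_pools, arm="bulk", rng=rng_pool
    )

    # singleton stage: every pooled candidate, in bulk and sorted arms
    rng_single = _rng(config.seed, "plate_single")
    plates_single = {}
    for arm in ("bulk", "CD4", "CD8"):
        hot = [
            pid
            for pid in pooled_ids
            if mutation_of[pid] in truth.immunogenic
            and _arm_recognizes(truth.immunogenic[mutation_of[pid]], arm)
        ]
        plates_single[arm] = gen_elispot_plate(
            config, pooled_ids, hot, arm=arm, rng=rng_single
        )

    return Fixture(
        config=config,
        proteome=proteome,
        variants=variants,
        truth=truth,
        peptides=peptides,
        pooled_peptide_ids=pooled_ids,
        pools=pools,
        plate_pool=plate_pool,
        plates_single=plates_single,
    )
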