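"""Synthetic ZW genome generator with a machine-readable truth ledger.

Emulates the structures a female-heterogametic (ZW) sex chromosome study
works with, at desk scale: a Z/W chromosome pair sharing byte-identical
pseudoautosomal regions (PARs) at both ends; a female sex-determination
region (SDR) carrying hemizygous insertions absent from Z; a two-palindrome
block whose four ~20-kb high-identity arms descend from one template; gene
conversion tracts that homogenize the arms within each of two diverged
sister species; LTR retrotransposon insertions whose two terminal repeats
diverge according to a known age; Poisson sexed read depth (female = Z+W,
male = 2Z, collapsed palindrome arms ~ 4 haplotype equivalents); and pooled
genotyping-by-sequencing (GBS) depths for offspring pools of each sex.

Every planted feature is recorded in a :class:`SyntheticTruth` ledger so
downstream detectors can be scored without any external data.  Coordinates
are 0-based half-open throughout this module.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import (
    arr_to_seq,
    evolve_arr,
    random_dna_arr,
    revcomp,
    seq_to_arr,
)

W_CHROM = "Chr15W"
Z_CHROM = "Chr15Z"


# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class LTRSpec:
    """One LTR retrotransposon insertion to plant.

    ``age_years`` and ``mutation_rate`` (substitutions/site/year) set the
    expected divergence between the two terminal repeats: each repeat
    accumulates age * rate substitutions per site after insertion.
    """

    age_years: float
    mutation_rate: float = 2.5e-9
    ltr_length: int = 1000
    internal_length: int = 4000
    tsd_length: int = 5

    def validate(self) -> list[str]:
        errors = []
        if not 5 <= self.tsd_length <= 20:
            errors.append(
                f"tsd_length {self.tsd_length} outside the allowed range [5, 20]"
            )
        if self.age_years < 0:
            errors.append("age_years must be >= 0")
        if self.mutation_rate <= 0:
            errors.append("mutation_rate must be > 0")
        if self.ltr_length <= 0 or self.internal_length <= 0:
            errors.append("ltr_length and internal_length must be > 0")
        return errors


def _default_ltr_specs() -> list[LTRSpec]:
    return [
        LTRSpec(age_years=1.0e6, tsd_length=5),
        LTRSpec(age_years=5.0e6, tsd_length=10),
        LTRSpec(age_years=8.6e6, tsd_length=15),
    ]


@dataclass(frozen=True)
class GeneSetConfig:
    """Sizes of the planted gene categories for the homology stage."""

    n_zw_pairs: int = 12
    n_w_tandem_arrays: int = 2
    tandem_array_size: int = 3
    n_transposed: int = 4
    n_ancestral: int = 3
    n_no_hit: int = 4
    n_autosome_background: int = 6
    min_codons: int = 120
    max_codons: int = 300
    zw_divergence: float = 0.03
    tandem_divergence: float = 0.02


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic ZW genome.

    The seed fully determines every output.  ``chrom_length`` is the length
    of the Z chromosome; W is longer by the planted W-specific material.
    """

    seed: int = 0
    chrom_length: int = 400_000
    par1_length: int = 60_000
    par2_length: int = 60_000
    n_hemizygous_insertions: int = 8
    insertion_length_range: tuple[int, int] = (5_000, 15_000)
    palindrome_arm_length: int = 20_000
    arm3b_length: int = 8_000
    spacer_length: int = 3_600
    inter_palindrome_gap: int = 2_700
    inner_arm_gap: int = 3_000  # unique sequence between nested P2 arm shells
    pre_arm_fraction: float = 0.6
    n_arms: int = 4
    arm_divergence: float = 0.01
    within_palindrome_divergence: float = 0.002
    conversion_tracts: tuple[tuple[int, int], ...] = ((5_000, 8_000),)
    species_divergence: float = 0.02
    zw_divergence: float = 0.03
    ltr_specs: tuple[LTRSpec, ...] = field(default_factory=lambda: tuple(_default_ltr_specs()))
    mean_depth_per_haplotype: float = 75.0
    gbs_interval_density: float = 600.0  # intervals per Mb
    per_offspring_gbs_depth: float = 2.0
    n_female_offspring: int = 195
    n_male_offspring: int = 195
    mismap_epsilon: float = 0.0
    indel_rate: float = 0.0
    indel_mean_length: float = 3.0
    gene_set: GeneSetConfig | None = field(default_factory=GeneSetConfig)

    def validate(self) -> list[str]:
        """Return every constraint violation (empty list when valid)."""
        errors: list[str] = []
        if self.chrom_length <= 0:
            errors.append("chrom_length must be > 0")
        if self.par1_length <= 0 or self.par2_length <= 0:
            errors.append("PAR lengths must be > 0")
        sdr = self.chrom_length - self.par1_length - self.par2_length
        if sdr <= 0:
            errors.append("PARs leave no room for an SDR")
        lo, hi = self.insertion_length_range
        if not 0 < lo <= hi:
            errors.append("insertion_length_range must satisfy 0 < lo <= hi")
        if self.n_arms not in (0, 2, 4):
            errors.append("n_arms must be 0, 2 or 4")
        if self.n_arms and self.palindrome_arm_length <= 0:
            errors.append("palindrome_arm_length must be > 0")
        if not 0 <= self.within_palindrome_divergence <= self.arm_divergence:
            errors.append(
                "within_palindrome_divergence must lie in [0, arm_divergence] "
                "(arms of one palindrome are at least as similar as arms of different palindromes)"
            )
        for s, e in self.conversion_tracts:
            if not 0 <= s < e <= self.palindrome_arm_length:
                errors.append(
                    f"conversion tract ({s}, {e}) outside [0, {self.palindrome_arm_length})"
                )
        for spec in self.ltr_specs:
            errors.extend(spec.validate())
        if self.mean_depth_per_haplotype <= 0:
            errors.append("mean_depth_per_haplotype must be > 0")
        n_anchors = self.n_hemizygous_insertions + (1 if self.n_arms else 0)
        if sdr > 0 and n_anchors and sdr < (n_anchors + 1) * 1_000:
            errors.append(
                "SDR too small to host the requested features "
                f"({n_anchors} anchors in {sdr} bp)"
            )
        return errors

    def require_valid(self) -> None:
        errors = self.validate()
        if errors:
            raise ValueError("invalid SimulationConfig: " + "; ".join(errors))


# --------------------------------------------------------------------------
# truth ledger records


@dataclass
class ArmRecord:
    label: str
    start: int
    end: int
    orientation: str  # '+' template orientation, '-' reverse complement
    arm_id: str  # template family ('main' 20-kb template or 'b' arm3b/4b)


@dataclass
class SpacerRecord:
    label: str
    start: int
    end: int


@dataclass
class LTRElementTruth:
    element_id: str
    five_prime: tuple[int, int]
    internal: tuple[int, int]
    three_prime: tuple[int, int]
    tsd: str
    true_age: float
    mutation_rate: float


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    category: str  # ZW_homolog | tandem | transposed_from_autosome | ancestral_lost_on_Z | none


@dataclass
class GeneSetTruth:
    """Planted protein/CDS sets with ground-truth category labels."""

    w_proteins: dict[str, str]
    z_proteins: dict[str, str]
    autosome_proteins: dict[str, str]
    outgroup_proteins: dict[str, str]
    w_cds: dict[str, str]
    z_cds: dict[str, str]
    positions: pd.DataFrame  # gene_id, chrom, start, end, strand
    categories: dict[str, str]  # truth label per W gene


@dataclass
class SyntheticTruth:
    """Ground-truth ledger for one simulated genome."""

    config: SimulationConfig
    z_sequence: str
    w_sequence: str
    sister_w_sequence: str
    hemizygous_intervals: list[tuple[int, int]]
    palindrome_layout: list[ArmRecord]
    spacers: list[SpacerRecord]
    pre_arm: tuple[int, int] | None
    conversion_tracts: list[tuple[int, int]]
    ltr_elements: list[LTRElementTruth]
    gene_models: list[GeneModel]
    arm_template: str
    arm_sequences: dict[str, str]  # template-oriented focal arms
    sister_arm_sequences: dict[str, str]
    sister_consensus: str
    gene_set: GeneSetTruth | None
    w_sdr: tuple[int, int]  # SDR interval on W
    z_sdr: tuple[int, int]

    # ---- derived views -------------------------------------------------

    def w_specific_mask(self) -> np.ndarray:
        """Boolean per-base mask over W of material with no Z counterpart."""
        mask = np.zeros(len(self.w_sequence), dtype=bool)
        for s, e in self.hemizygous_intervals:
            mask[s:e] = True
        return mask

    def hemizygous_fraction_of_sdr(self) -> float:
        s, e = self.w_sdr
        mask = self.w_specific_mask()
        return float(mask[s:e].mean())

    def main_arm_labels(self) -> list[str]:
        return [a.label for a in self.palindrome_layout if a.arm_id == "main"]


def expected_hemizygous_fraction(config: SimulationConfig) -> float:
    """Expected fraction of the W-SDR covered by hemizygous truth intervals.

    Direct interval arithmetic on the configured feature sizes: random
    insertions enter at their mean length; the palindrome block and LTR
    elements are deterministic in size.
    """
    lo, hi = config.insertion_length_range
    ins = config.n_hemizygous_insertions * (lo + hi) / 2.0
    block = _palindrome_block_length(config)
    ltr = sum(2 * s.ltr_length + s.internal_length + s.tsd_length for s in config.ltr_specs)
    sdr_z = config.chrom_length - config.par1_length - config.par2_length
    specific = ins + block + ltr
    return specific / (sdr_z + specific)


def _palindrome_block_length(config: SimulationConfig) -> int:
    if config.n_arms == 0:
        return 0
    arm = config.palindrome_arm_length
    pre = int(round(config.pre_arm_fraction * arm))
    p1 = pre + arm + config.spacer_length + arm
    if config.n_arms == 2:
        return p1
    p2 = arm + config.arm3b_length + config.arm3b_length + arm + 2 * config.inner_arm_gap
    return p1 + config.inter_palindrome_gap + p2


# --------------------------------------------------------------------------
# palindrome construction


def plant_palindrome(
    sequence: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    at: int | None = None,
) -> tuple[str, dict]:
    """Insert a two-palindrome block into ``sequence`` and return the layout.

    The block reads (coordinates relative to the insertion point)::

        pre-arm | arm1(+) spacer1 arm2(-) | gap | arm3a(+) arm3b(+) arm4b(-) arm4a(-)

    arm1/arm2/arm3a/arm4a descend from one template ("main" family) and
    arm3b/arm4b from a second template.  Divergence is hierarchical: each
    palindrome has its own consensus evolved from the template, and arms
    within a palindrome evolve only ``within_palindrome_divergence/2`` from
    that consensus — so within-palindrome pairs are far more similar than
    cross-palindrome pairs, as ongoing arm conversion maintains.  The
    pre-arm is a partial direct copy from the first palindrome's consensus
    abutting arm1.  With ``n_arms == 2`` only the first palindrome (and
    pre-arm) is planted.
    """
    if config.n_arms == 0:
        return sequence, {"arms": [], "spacers": [], "pre_arm": None, "block": None}
    if at is None:
        at = len(sequence) // 2
    if not 0 <= at <= len(sequence):
        raise ValueError("placement position outside the sequence")
    if at < config.par1_length or at > len(sequence) - config.par2_length:
        raise ValueError("palindrome arms would overlap the PARs")

    arm_len = config.palindrome_arm_length
    # divergence hierarchy: arms of one palindrome descend from a shared
    # per-palindrome consensus (ongoing conversion keeps them near-identical)
    # while the consensuses of different palindromes sit deeper on the tree,
    # so pairwise divergence is ~within_palindrome_divergence inside a
    # palindrome and ~arm_divergence across palindromes
    per_copy = config.within_palindrome_divergence / 2.0
    per_consensus = max(config.arm_divergence - config.within_palindrome_divergence, 0.0) / 2.0
    template = random_dna_arr(rng, arm_len)
    template_b = random_dna_arr(rng, config.arm3b_length)
    consensus_p1 = evolve_arr(template, rng, per_consensus)
    consensus_p2 = evolve_arr(template, rng, per_consensus)

    def copy_of(consensus: np.ndarray) -> np.ndarray:
        arr = evolve_arr(consensus, rng, per_copy)
        if config.indel_rate > 0:
            arr = _apply_indels(arr, rng, config.indel_rate, config.indel_mean_length)
        return arr

    arm_arrs: dict[str, np.ndarray] = {}
    pieces: list[tuple[str, str, str, str]] = []  # (kind, label, seq, family)

    pre_len = int(round(config.pre_arm_fraction * arm_len))
    pre_src = copy_of(consensus_p1)[:pre_len]
    pieces.append(("pre_arm", "pre-arm", arr_to_seq(pre_src), "main"))

    for label in ("arm1", "arm2"):
        arm_arrs[label] = copy_of(consensus_p1)
    pieces.append(("arm+", "arm1", arr_to_seq(arm_arrs["arm1"]), "main"))
    pieces.append(("spacer", "spacer1", arr_to_seq(random_dna_arr(rng, config.spacer_length)), ""))
    pieces.append(("arm-", "arm2", arr_to_seq(arm_arrs["arm2"]), "main"))

    if config.n_arms == 4:
        for label in ("arm3a", "arm4a"):
            arm_arrs[label] = copy_of(consensus_p2)
        b3 = copy_of(template_b)
        b4 = copy_of(template_b)
        pieces.append(("gap", "gap12", arr_to_seq(random_dna_arr(rng, config.inter_palindrome_gap)), ""))
        pieces.append(("arm+", "arm3a", arr_to_seq(arm_arrs["arm3a"]), "main"))
        pieces.append(("gap", "gap3", arr_to_seq(random_dna_arr(rng, config.inner_arm_gap)), ""))
        pieces.append(("arm+", "arm3b", arr_to_seq(b3), "b"))
        pieces.append(("arm-", "arm4b", arr_to_seq(b4), "b"))
        pieces.append(("gap", "gap4", arr_to_seq(random_dna_arr(rng, config.inner_arm_gap)), ""))
        pieces.append(("arm-", "arm4a", arr_to_seq(arm_arrs["arm4a"]), "main"))
        arm_arrs["arm3b"] = b3
        arm_arrs["arm4b"] = b4

    arms: list[ArmRecord] = []
    spacers: list[SpacerRecord] = []
    pre_arm = None
    cursor = at
    block_parts: list[str] = []
    for kind, label, seq, family in pieces:
        emitted = revcomp(seq) if kind == "arm-" else seq
        start, end = cursor, cursor + len(emitted)
        if kind in ("arm+", "arm-"):
            arms.append(ArmRecord(label, start, end, "+" if kind == "arm+" else "-", family))
        elif kind == "spacer":
            spacers.append(SpacerRecord(label, start, end))
        elif kind == "pre_arm":
            pre_arm = (start, end)
        block_parts.append(emitted)
        cursor = end

    block = "".join(block_parts)
    new_seq = sequence[:at] + block + sequence[at:]
    layout = {
        "arms": arms,
        "spacers": spacers,
        "pre_arm": pre_arm,
        "block": (at, at + len(block)),
        "arm_sequences": {k: arr_to_seq(v) for k, v in arm_arrs.items()},
        "template": arr_to_seq(template),
    }
    return new_seq, layout


def _apply_indels(
    arr: np.ndarray, rng: np.random.Generator, rate: float, mean_length: float
) -> np.ndarray:
    """Optional indel mode: geometric-length insertions/deletions."""
    n = rng.poisson(rate * arr.size)
    if n == 0:
        return arr
    out = list(arr)
    for _ in range(n):
        pos = int(rng.integers(0, max(len(out), 1)))
        length = int(rng.geometric(1.0 / mean_length))
        if rng.random() < 0.5:
            del out[pos : pos + length]
        else:
            out[pos:pos] = list(random_dna_arr(rng, length))
    return np.array(out, dtype=np.uint8)


# --------------------------------------------------------------------------
# gene conversion


def apply_gene_conversion(truth: SyntheticTruth) -> SyntheticTruth:
    """Homogenize the main palindrome arms within each species inside tracts.

    Within every conversion tract (arm-template coordinates) each focal-species
    arm is overwritten with the focal consensus (the arm template) and each
    sister-species arm with the sister consensus, so no paralogous sequence
    variants (PSVs) survive inside the tract while interspecific fixed
    differences are preserved.  Outside the tracts arm-private variants
    persist.  Returns the modified truth (in place).
    """
    if truth.config.indel_rate > 0:
        raise ValueError("gene conversion homogenization requires the no-indel substitution model")
    for s, e in truth.conversion_tracts:
        if not 0 <= s < e <= len(truth.arm_template):
            raise ValueError(f"conversion tract ({s}, {e}) outside the arm template")
    consensus = {
        "focal": truth.arm_template,
        "sister": truth.sister_consensus,
    }
    for species, arm_seqs, genome_attr in (
        ("focal", truth.arm_sequences, "w_sequence"),
        ("sister", truth.sister_arm_sequences, "sister_w_sequence"),
    ):
        if not arm_seqs:
            continue
        genome = getattr(truth, genome_attr)
        cons = consensus[species]
        for rec in truth.palindrome_layout:
            if rec.arm_id != "main":
                continue
            arm = list(arm_seqs[rec.label])
            for s, e in truth.conversion_tracts:
                arm[s:e] = cons[s:e]
            arm_seq = "".join(arm)
            arm_seqs[rec.label] = arm_seq
            emitted = arm_seq if rec.orientation == "+" else revcomp(arm_seq)
            genome = genome[: rec.start] + emitted + genome[rec.end :]
        setattr(truth, genome_attr, genome)
    return truth


def simulate_sister_species(
    truth: SyntheticTruth,
    divergence: float | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Derive the sister-species W haplotype.

    A copy of W with additional substitutions at the configured interspecific
    rate; the main palindrome arms are re-derived from a sister-specific
    consensus so that, after :func:`apply_gene_conversion`, converted tracts
    carry interspecific fixed differences but no within-species PSVs.
    Populates ``truth.sister_w_sequence``, ``truth.sister_consensus`` and
    ``truth.sister_arm_sequences`` and returns the sister sequence.
    """
    if divergence is None:
        divergence = truth.config.species_divergence
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    if rng is None:
        rng = np.random.default_rng((truth.config.seed, 0x5157))
    sister = arr_to_seq(evolve_arr(seq_to_arr(truth.w_sequence), rng, divergence))
    sister_consensus = arr_to_seq(evolve_arr(seq_to_arr(truth.arm_template), rng, divergence))
    per_copy = truth.config.arm_divergence / 2.0
    sister_arms: dict[str, str] = {}
    for rec in truth.palindrome_layout:
        if rec.arm_id != "main":
            continue
        arm = arr_to_seq(evolve_arr(seq_to_arr(sister_consensus), rng, per_copy))
        sister_arms[rec.label] = arm
        emitted = arm if rec.orientation == "+" else revcomp(arm)
        sister = sister[: rec.start] + emitted + sister[rec.end :]
    truth.sister_w_sequence = sister
    truth.sister_consensus = sister_consensus
    truth.sister_arm_sequences = sister_arms
    return sister


# --------------------------------------------------------------------------
# LTR insertion


def simulate_ltr_insertion(
    sequence: str,
    spec: LTRSpec,
    rng: np.random.Generator,
    at: int | None = None,
    element_id: str = "ltr-1",
) -> tuple[str, LTRElementTruth]:
    """Insert one LTR retrotransposon with a duplicated target site.

    The element (5' LTR + internal + 3' LTR) is inserted after position
    ``at``; the ``tsd_length`` bases upstream of the insertion point are
    duplicated downstream of the element, mimicking target site duplication.
    Each terminal repeat is then mutated independently with an expected
    age * mutation_rate substitutions per site.
    """
    errors = spec.validate()
    if errors:
        raise ValueError("; ".join(errors))
    min_pos = spec.tsd_length
    if len(sequence) < min_pos + 1:
        raise ValueError("sequence too short to host an LTR element")
    if at is None:
        at = int(rng.integers(min_pos, len(sequence)))
    if at < min_pos:
        raise ValueError("insertion point leaves no room for the target site duplication")
    tsd = sequence[at - spec.tsd_length : at]
    ltr0 = random_dna_arr(rng, spec.ltr_length)
    internal = arr_to_seq(random_dna_arr(rng, spec.internal_length))
    d = spec.age_years * spec.mutation_rate
    five = arr_to_seq(evolve_arr(ltr0, rng, d))
    three = arr_to_seq(evolve_arr(ltr0, rng, d))
    element = five + internal + three + tsd
    new_seq = sequence[:at] + element + sequence[at:]
    f0 = at
    rec = LTRElementTruth(
        element_id=element_id,
        five_prime=(f0, f0 + spec.ltr_length),
        internal=(f0 + spec.ltr_length, f0 + spec.ltr_length + spec.internal_length),
        three_prime=(
            f0 + spec.ltr_length + spec.internal_length,
            f0 + 2 * spec.ltr_length + spec.internal_length,
        ),
        tsd=tsd,
        true_age=spec.age_years,
        mutation_rate=spec.mutation_rate,
    )
    return new_seq, rec


# --------------------------------------------------------------------------
# gene sets


_STOPS = {"TAA", "TAG", "TGA"}
_CODON_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


def translate(cds: str) -> str:
    table = _codon_table()
    return "".join(table[cds[i : i + 3]] for i in range(0, len(cds) - len(cds) % 3, 3))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    out = []
    while len(out) < n_codons:
        codon = arr_to_seq(random_dna_arr(rng, 3))
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def _evolve_cds(cds: str, rng: np.random.Generator, d: float) -> str:
    arr = evolve_arr(seq_to_arr(cds), rng, d)
    out = arr_to_seq(arr)
    codons = [out[i : i + 3] for i in range(0, len(out), 3)]
    fixed = [c if c not in _STOPS else cds[i * 3 : i * 3 + 3] for i, c in enumerate(codons)]
    return "".join(fixed)


def simulate_strata_pairs(
    rng: np.random.Generator,
    strata: tuple[tuple[float, int], ...] = ((0.02, 15), (0.08, 15)),
    n_codons: int = 200,
    gene_spacing: int = 20_000,
) -> list[tuple[str, str, int]]:
    """Z-W CDS pairs laid along Z with stratum-specific divergence.

    ``strata`` is a tuple of (pairwise divergence, n_genes) blocks in Z
    order; genes sit every ``gene_spacing`` bp.  Returns (w_cds, z_cds,
    z_position) triples — the input for a dS-vs-position strata scan with a
    known number of true strata.
    """
    out = []
    pos = 10_000
    for divergence, n_genes in strata:
        for _ in range(n_genes):
            z = _random_cds(rng, n_codons)
            w = _evolve_cds(z, rng, divergence)
            out.append((w, z, pos))
            pos += gene_spacing
    return out


def simulate_gene_sets(rng: np.random.Generator, cfg: GeneSetConfig) -> GeneSetTruth:
    """Plant W/Z/autosome/outgroup gene sets with known category labels.

    Gene coordinates are abstract annotations (one gene every ~20 kb on its
    chromosome); tandem array members are placed within a 500-kb window.
    """
    w_cds: dict[str, str] = {}
    z_cds: dict[str, str] = {}
    a_cds: dict[str, str] = {}
    o_cds: dict[str, str] = {}
    categories: dict[str, str] = {}
    rows: list[dict] = []
    counters = {"Chr15W": 0, "Chr15Z": 0, "Chr01": 0, "outChr15": 0}

    def place(gene_id: str, chrom: str, length_nt: int, spacing: int = 20_000) -> None:
        i = counters[chrom]
        counters[chrom] += 1
        start = 10_000 + i * spacing
        rows.append(
            {"gene_id": gene_id, "chrom": chrom, "start": start, "end": start + length_nt, "strand": "+"}
        )

    def codons() -> int:
        return int(rng.integers(cfg.min_codons, cfg.max_codons + 1))

    for i in range(cfg.n_zw_pairs):
        base = _random_cds(rng, codons())
        zid, wid = f"zw{i:03d}.Z", f"zw{i:03d}.W"
        z_cds[zid] = base
        w_cds[wid] = _evolve_cds(base, rng, cfg.zw_divergence)
        categories[wid] = "ZW_homolog"
        place(wid, "Chr15W", len(base))
        place(zid, "Chr15Z", len(base))

    for a in range(cfg.n_w_tandem_arrays):
        base = _random_cds(rng, codons())
        anchor = 10_000 + counters["Chr15W"] * 20_000
        for m in range(cfg.tandem_array_size):
            gid = f"wtand{a}{chr(ord('a') + m)}.W"
            w_cds[gid] = _evolve_cds(base, rng, cfg.tandem_divergence)
            categories[gid] = "tandem"
            start = anchor + m * 30_000  # well inside one 500-kb window
            rows.append(
                {"gene_id": gid, "chrom": "Chr15W", "start": start, "end": start + len(base), "strand": "+"}
            )
        counters["Chr15W"] += cfg.tandem_array_size * 2

    for i in range(cfg.n_transposed):
        base = _random_cds(rng, codons())
        aid, wid = f"auto{i:03d}.A", f"trans{i:03d}.W"
        a_cds[aid] = base
        w_cds[wid] = _evolve_cds(base, rng, cfg.tandem_divergence)
        categories[wid] = "transposed_from_autosome"
        place(wid, "Chr15W", len(base))
        place(aid, "Chr01", len(base))

    for i in range(cfg.n_ancestral):
        base = _random_cds(rng, codons())
        oid, wid = f"anc{i:03d}.O", f"anc{i:03d}.W"
        o_cds[oid] = base
        w_cds[wid] = _evolve_cds(base, rng, 0.08)  # outgroup split is older
        categories[wid] = "ancestral_lost_on_Z"
        place(wid, "Chr15W", len(base))
        place(oid, "outChr15", len(base))

    for i in range(cfg.n_no_hit):
        gid = f"orphan{i:03d}.W"
        w_cds[gid] = _random_cds(rng, codons())
        categories[gid] = "none"
        place(gid, "Chr15W", len(w_cds[gid]))

    for i in range(cfg.n_autosome_background):
        gid = f"bg{i:03d}.A"
        a_cds[gid] = _random_cds(rng, codons())
        place(gid, "Chr01", len(a_cds[gid]))

    return GeneSetTruth(
        w_proteins={k: translate(v) for k, v in w_cds.items()},
        z_proteins={k: translate(v) for k, v in z_cds.items()},
        autosome_proteins={k: translate(v) for k, v in a_cds.items()},
        outgroup_proteins={k: translate(v) for k, v in o_cds.items()},
        w_cds=w_cds,
        z_cds=z_cds,
        positions=pd.DataFrame(rows),
        categories=categories,
    )


# --------------------------------------------------------------------------
# genome assembly


def simulate_zw_pair(config: SimulationConfig) -> SyntheticTruth:
    """Generate a Z/W chromosome pair plus sister species with full truth.

    W = PAR1 + W-SDR + PAR2 where the SDR shares a diverged backbone with Z
    and additionally carries hemizygous insertions, the palindrome block and
    LTR elements; Z shares the PARs byte-identically.
    """
    config.require_valid()
    rng = np.random.default_rng(config.seed)

    par1 = arr_to_seq(random_dna_arr(rng, config.par1_length))
    par2 = arr_to_seq(random_dna_arr(rng, config.par2_length))
    sdr_z_len = config.chrom_length - config.par1_length - config.par2_length
    z_backbone_arr = random_dna_arr(rng, sdr_z_len)
    z_backbone = arr_to_seq(z_backbone_arr)
    w_backbone = arr_to_seq(evolve_arr(z_backbone_arr, rng, config.zw_divergence))

    n_features = config.n_hemizygous_insertions + (1 if config.n_arms else 0)
    if n_features:
        margin = max(sdr_z_len // (n_features * 4), 200)
        anchors = np.sort(
            rng.choice(
                np.arange(margin, sdr_z_len - margin), size=n_features, replace=False
            )
        )
    else:
        anchors = np.array([], dtype=int)
    # the palindrome block goes to the middle anchor; insertions elsewhere
    feature_kinds = ["insertion"] * config.n_hemizygous_insertions
    if config.n_arms:
        feature_kinds.insert(len(feature_kinds) // 2, "palindrome")

    lo, hi = config.insertion_length_range
    segments: list[str] = [par1]
    cursor_backbone = 0
    abs_pos = len(par1)
    hemizygous: list[tuple[int, int]] = []
    layout: dict = {"arms": [], "spacers": [], "pre_arm": None, "block": None}
    arm_sequences: dict[str, str] = {}
    arm_template = ""

    for anchor, kind in zip(anchors, feature_kinds):
        chunk = w_backbone[cursor_backbone:anchor]
        segments.append(chunk)
        abs_pos += len(chunk)
        cursor_backbone = anchor
        if kind == "insertion":
            length = int(rng.integers(lo, hi + 1))
            ins = arr_to_seq(random_dna_arr(rng, length))
            segments.append(ins)
            hemizygous.append((abs_pos, abs_pos + length))
            abs_pos += length
        else:
            # plant the block at offset 0 of an empty carrier, then shift
            block_seq, lay = plant_palindrome("", _unbounded(config), rng, at=0)
            segments.append(block_seq)
            shift = abs_pos
            layout = {
                "arms": [
                    ArmRecord(a.label, a.start + shift, a.end + shift, a.orientation, a.arm_id)
                    for a in lay["arms"]
                ],
                "spacers": [
                    SpacerRecord(s.label, s.start + shift, s.end + shift) for s in lay["spacers"]
                ],
                "pre_arm": (lay["pre_arm"][0] + shift, lay["pre_arm"][1] + shift)
                if lay["pre_arm"]
                else None,
                "block": (shift, shift + len(block_seq)),
            }
            arm_sequences = lay["arm_sequences"]
            arm_template = lay["template"]
            hemizygous.append((abs_pos, abs_pos + len(block_seq)))
            abs_pos += len(block_seq)
    segments.append(w_backbone[cursor_backbone:])
    abs_pos += sdr_z_len - cursor_backbone
    segments.append(par2)

    w_sequence = "".join(segments)
    w_sdr = (config.par1_length, len(w_sequence) - config.par2_length)
    z_sequence = par1 + z_backbone + par2

    truth = SyntheticTruth(
        config=config,
        z_sequence=z_sequence,
        w_sequence=w_sequence,
        sister_w_sequence="",
        hemizygous_intervals=hemizygous,
        palindrome_layout=layout["arms"],
        spacers=layout["spacers"],
        pre_arm=layout["pre_arm"],
        conversion_tracts=[tuple(t) for t in config.conversion_tracts] if config.n_arms else [],
        ltr_elements=[],
        gene_models=[],
        arm_template=arm_template,
        arm_sequences=arm_sequences,
        sister_arm_sequences={},
        sister_consensus="",
        gene_set=None,
        w_sdr=w_sdr,
        z_sdr=(config.par1_length, config.par1_length + sdr_z_len),
    )

    # LTR elements inserted into ZW-homologous backbone inside the SDR,
    # clear of the palindrome block (their whole span becomes W-specific)
    block = layout["block"]
    for i, spec in enumerate(config.ltr_specs):
        span = 2 * spec.ltr_length + spec.internal_length + spec.tsd_length
        for _ in range(200):
            at = int(rng.integers(truth.w_sdr[0] + spec.tsd_length, truth.w_sdr[1]))
            if _clear_of_features(at, truth, block, spec.tsd_length):
                break
        else:
            raise ValueError("SDR too small to host the requested LTR elements")
        new_w, rec = simulate_ltr_insertion(
            truth.w_sequence, spec, rng, at=at, element_id=f"ltr-{i + 1}"
        )
        truth.w_sequence = new_w
        _shift_truth(truth, at, span)
        if block is not None and at <= block[0]:
            block = (block[0] + span, block[1] + span)
        truth.ltr_elements.append(rec)
        truth.hemizygous_intervals.append((rec.five_prime[0], rec.three_prime[1] + spec.tsd_length))
    truth.hemizygous_intervals.sort()

    # sister species + gene conversion homogenization
    simulate_sister_species(truth, config.species_divergence, rng)
    if truth.conversion_tracts and config.n_arms:
        apply_gene_conversion(truth)

    if config.gene_set is not None:
        gs = simulate_gene_sets(rng, config.gene_set)
        truth.gene_set = gs
        truth.gene_models = [
            GeneModel(
                gene_id=r.gene_id,
                chrom=r.chrom,
                start=int(r.start),
                end=int(r.end),
                strand=r.strand,
                category=gs.categories.get(r.gene_id, "none"),
            )
            for r in gs.positions.itertuples()
        ]
    return truth


def _unbounded(config: SimulationConfig) -> SimulationConfig:
    """Config clone whose PAR bounds don't constrain block-local planting."""
    return dataclasses.replace(config, par1_length=0, par2_length=0, chrom_length=config.chrom_length)


def _clear_of_features(at: int, truth: SyntheticTruth, block, tsd_len: int) -> bool:
    lo, hi = at - tsd_len - 5, at + 5
    if block is not None and not (hi <= block[0] or lo >= block[1]):
        return False
    for s, e in truth.hemizygous_intervals:
        if not (hi <= s or lo >= e):
            return False
    return True


def _shift_truth(truth: SyntheticTruth, at: int, length: int) -> None:
    """Shift all recorded W intervals at or beyond ``at`` by ``length``."""

    def shift_iv(iv):
        s, e = iv
        return (s + length if s >= at else s, e + length if e > at else e)

    truth.hemizygous_intervals = [shift_iv(iv) for iv in truth.hemizygous_intervals]
    for a in truth.palindrome_layout:
        a.start, a.end = shift_iv((a.start, a.end))
    for sp in truth.spacers:
        sp.start, sp.end = shift_iv((sp.start, sp.end))
    if truth.pre_arm is not None:
        truth.pre_arm = shift_iv(truth.pre_arm)
    truth.ltr_elements = [
        dataclasses.replace(
            el,
            five_prime=shift_iv(el.five_prime),
            internal=shift_iv(el.internal),
            three_prime=shift_iv(el.three_prime),
        )
        for el in truth.ltr_elements
    ]
    s, e = truth.w_sdr
    truth.w_sdr = (s, e + length)
    # sister sequence tracks W coordinates; re-derived afterwards, so only
    # shift if already present
    if truth.sister_w_sequence:
        truth.sister_w_sequence = (
            truth.sister_w_sequence[:at] + "N" * length + truth.sister_w_sequence[at:]
        )


# --------------------------------------------------------------------------
# sequencing-depth simulation


@dataclass
class DepthTrack:
    """Per-base read depth along one sequence."""

    chrom: str
    depth: np.ndarray
    start: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": np.arange(self.start, self.start + self.depth.size),
                "depth": self.depth,
            }
        )


def simulate_read_depth(
    truth: SyntheticTruth,
    sex: str,
    mean_depth: float | None = None,
    rng: np.random.Generator | None = None,
) -> DepthTrack:
    """Poisson per-base depth of one sex's reads aligned to the W reference.

    Expected copy number per base: 2 haplotypes over PARs and Z-W homologous
    SDR for both sexes; 1 haplotype over W-specific material in females and
    ``mismap_epsilon`` haplotype-equivalents in males.
    """
    if sex not in ("female", "male"):
        raise ValueError(f"unknown sex label {sex!r} (expected 'female' or 'male')")
    if mean_depth is None:
        mean_depth = truth.config.mean_depth_per_haplotype
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if rng is None:
        rng = np.random.default_rng((truth.config.seed, 0xDE01, sex == "female"))
    mask = truth.w_specific_mask()
    eps = truth.config.mismap_epsilon
    copies = np.where(mask, 1.0 if sex == "female" else eps, 2.0)
    depth = rng.poisson(copies * mean_depth)
    return DepthTrack(chrom=W_CHROM, depth=depth)


def simulate_collapsed_arm_depth(
    truth: SyntheticTruth,
    mean_depth_per_arm: float = 15.0,
    rng: np.random.Generator | None = None,
) -> DepthTrack:
    """Female read depth on a single-arm reference collapsing all main arms.

    Each of the four near-identical arms contributes one haplotype
    equivalent, so expectation is 4 * per-arm depth while the genome-wide
    diploid expectation is 2 * per-arm depth ("2N"), i.e. the collapsed
    region sits at ~4N.
    """
    if rng is None:
        rng = np.random.default_rng((truth.config.seed, 0xDE02))
    n_arms = len(truth.main_arm_labels())
    depth = rng.poisson(n_arms * mean_depth_per_arm, size=len(truth.arm_template))
    return DepthTrack(chrom="arm1_ref", depth=depth)


def simulate_collapsed_pileup(
    truth: SyntheticTruth,
    mean_depth_per_arm: float = 15.0,
    rng: np.random.Generator | None = None,
    base_qual: float = 60.0,
) -> pd.DataFrame:
    """Variant sites from focal + sister reads collapsed onto arm 1.

    For each template position, each main arm of each species contributes a
    Poisson(per-arm depth) read count carrying its own allele.  Sites where
    any sampled read disagrees with the arm-1 reference are emitted with
    per-species reference/alternate depths, a site quality and the truth
    classification (psv_focal, psv_sister, shared_variant, fixed_difference).
    """
    if not truth.arm_sequences:
        raise ValueError("truth has no palindrome arms")
    if rng is None:
        rng = np.random.default_rng((truth.config.seed, 0xDE03))
    labels = truth.main_arm_labels()
    focal = np.stack([seq_to_arr(truth.arm_sequences[k]) for k in labels])
    sister = np.stack([seq_to_arr(truth.sister_arm_sequences[k]) for k in labels])
    ref = focal[0]
    n_arms, n = focal.shape
    depths_f = rng.poisson(mean_depth_per_arm, size=(n_arms, n))
    depths_s = rng.poisson(mean_depth_per_arm, size=(n_arms, n))

    focal_var = (focal != ref).any(axis=0)
    sister_var = (sister != ref).any(axis=0)
    candidate = np.nonzero(focal_var | sister_var)[0]

    rows = []
    for pos in candidate:
        f_alleles, s_alleles = focal[:, pos], sister[:, pos]
        alt_candidates = [a for a in np.concatenate([f_alleles, s_alleles]) if a != ref[pos]]
        # most frequent non-reference allele becomes the alt
        vals, counts = np.unique(alt_candidates, return_counts=True)
        alt = int(vals[np.argmax(counts)])
        f_ref = int(depths_f[f_alleles == ref[pos], pos].sum())
        f_alt = int(depths_f[f_alleles == alt, pos].sum())
        s_ref = int(depths_s[s_alleles == ref[pos], pos].sum())
        s_alt = int(depths_s[s_alleles == alt, pos].sum())
        if f_alt + s_alt == 0:
            continue  # no read sampled the variant allele
        f_psv = len(set(f_alleles)) > 1
        s_psv = len(set(s_alleles)) > 1
        if f_psv and s_psv:
            truth_class = "shared_variant"
        elif f_psv or s_psv:
            truth_class = "psv_focal" if f_psv else "psv_sister"
        elif f_alleles[0] != s_alleles[0]:
            truth_class = "fixed_difference"
        else:
            truth_class = "other"
        rows.append(
            {
                "pos": int(pos),
                "ref": "AGCT"[ref[pos]],
                "alt": "AGCT"[alt],
                "qual": float(base_qual + rng.normal(0, 3)),
                "depth": f_ref + f_alt,
                "depth_A_ref": f_ref,
                "depth_A_alt": f_alt,
                "depth_B_ref": s_ref,
                "depth_B_alt": s_alt,
                "truth_class": truth_class,
            }
        )
    cols = [
        "pos", "ref", "alt", "qual", "depth",
        "depth_A_ref", "depth_A_alt", "depth_B_ref", "depth_B_alt", "truth_class",
    ]
    return pd.DataFrame(rows, columns=cols)


def simulate_pooled_gbs(
    truth: SyntheticTruth,
    n_female: int | None = None,
    n_male: int | None = None,
    rng: np.random.Generator | None = None,
    density: float | None = None,
) -> pd.DataFrame:
    """Sparse GBS-like intervals with pooled-by-sex and resequencing depths.

    Columns: chrom, start, end, pooled_F, pooled_M, reseq_F, reseq_M.
    Pooled depths are Poisson with mean offspring_count * per-offspring depth
    * copies/2; hemizygous intervals have ~zero male pooled depth.
    """
    cfg = truth.config
    n_female = cfg.n_female_offspring if n_female is None else n_female
    n_male = cfg.n_male_offspring if n_male is None else n_male
    if n_female <= 0 or n_male <= 0:
        raise ValueError("offspring counts must be > 0")
    if density is None:
        density = cfg.gbs_interval_density
    if rng is None:
        rng = np.random.default_rng((cfg.seed, 0x6B5))
    w_len = len(truth.w_sequence)
    n_intervals = max(int(round(density * w_len / 1e6)), 2)
    starts = np.sort(rng.choice(w_len - 400, size=n_intervals, replace=False))
    lengths = rng.integers(80, 301, size=n_intervals)
    mask = truth.w_specific_mask()
    eps = cfg.mismap_epsilon
    d = cfg.per_offspring_gbs_depth
    hap = cfg.mean_depth_per_haplotype
    rows = []
    prev_end = -1
    for s, L in zip(starts, lengths):
        e = min(int(s) + int(L), w_len)
        if s <= prev_end:
            continue
        prev_end = e
        frac = mask[s:e].mean()
        c_f = 2.0 - frac  # females: 2 copies homologous, 1 on W-specific
        c_m = 2.0 * (1 - frac) + eps * frac
        rows.append(
            {
                "chrom": W_CHROM,
                "start": int(s),
                "end": e,
                "pooled_F": int(rng.poisson(n_female * d * c_f / 2.0)),
                "pooled_M": int(rng.poisson(n_male * d * c_m / 2.0)),
                "reseq_F": int(rng.poisson(hap * c_f)),
                "reseq_M": int(rng.poisson(hap * c_m)),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# serialization


def write_truth(truth: SyntheticTruth, outdir: str | Path) -> dict[str, Path]:
    """Serialize sequences and the ledger (FASTA + BED + GFF3 + JSON)."""
    from . import io as wio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["fasta"] = outdir / "genome.fasta"
    wio.write_fasta(
        paths["fasta"],
        {
            W_CHROM: truth.w_sequence,
            Z_CHROM: truth.z_sequence,
            "sister_" + W_CHROM: truth.sister_w_sequence,
        },
    )
    paths["hemizygous_bed"] = outdir / "hemizygous_truth.bed"
    wio.write_bed(
        paths["hemizygous_bed"],
        [(W_CHROM, s, e, f"hemi_{i}") for i, (s, e) in enumerate(truth.hemizygous_intervals)],
    )
    paths["palindrome_bed"] = outdir / "palindrome_truth.bed"
    feats = [(W_CHROM, a.start, a.end, f"{a.label}({a.orientation})") for a in truth.palindrome_layout]
    feats += [(W_CHROM, s.start, s.end, s.label) for s in truth.spacers]
    if truth.pre_arm:
        feats.append((W_CHROM, truth.pre_arm[0], truth.pre_arm[1], "pre-arm"))
    wio.write_bed(paths["palindrome_bed"], feats)
    paths["ltr_gff"] = outdir / "ltr_truth.gff3"
    wio.write_ltr_gff3(paths["ltr_gff"], W_CHROM, truth.ltr_elements)
    paths["config_json"] = outdir / "config.json"
    cfg = dataclasses.asdict(truth.config)
    paths["config_json"].write_text(json.dumps(cfg, indent=2, default=str) + "\n")
    return paths
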