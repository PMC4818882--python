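"""Seeded synthetic datasets emulating the colonial RNA-seq study design.

The emulated design: 5 colonies, each split into subclones sampled at the
three blastogenetic phases (mid-cycle MC, pre-take-over preTO, take-over
TO), one sequencing library per subclone.  Counts for gene g in sample s
are Poisson with mean

    N * theta_g * 2**phi[g, phase(s)] * eps[g, colony(s)]

where N is the target library size, theta_g a log-normal baseline relative
abundance normalized to sum to one, phi a per-phase log2 offset, and eps a
mild log-normal colony effect shared across phases within a colony (so it
cancels in within-colony phase comparisons, mimicking paired subclones).

A differentially expressed gene is shifted in exactly one phase, so it is
non-null on the two cyclic transitions adjacent to that phase and the three
per-gene transition effects sum to zero — the cycle returns to the same
state each week.  Genes are made phase-affected with probability
de_fraction * P/2 (P phases), which makes the per-transition count of
non-null genes exactly Binomial(n_genes, de_fraction).

The generator also emits toy transcripts of the five ORF-completeness
classes and a 13-column best-hit table, so the recovery stage is testable
without any alignment run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .pairwise_de import CountExperiment
from .transcript_recovery import (
    HIT_TABLE_COLUMNS,
    STOP_CODONS,
    Completeness,
    TranscriptRecord,
)

GO_DOMAINS = ("Biological Processes", "Molecular functions", "Cellular components")

#: taxa used for synthetic best-hit tables, host class first
HIT_TAXA = (
    "Ascidiacea", "Mammalia", "Actinopteri", "Aves", "Insecta",
    "Gastropoda", "Hydrozoa", "Eurotiomycetes",
)
HIT_TAXA_WEIGHTS = (0.70, 0.08, 0.06, 0.04, 0.04, 0.04, 0.02, 0.02)

ORF_CLASSES: tuple[Completeness, ...] = (
    "complete", "open5", "open3", "open_both", "none",
)

# codon pair creating stops in both shifted frames (TAA at +1, TGA at +2)
# while reading CTA-AGT-GAC in the design frame; sprinkled through random
# stretches it caps spurious cross-frame ORFs well below min_aa.
_FRAME_BLOCKER = "CTAAGTGAC"
_BLOCK_EVERY = 25

# sense codons excluding ATG and stops: random stretches can never create
# an in-frame start or stop except where the generator places one.
_SAFE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS and a + b + c != "ATG"
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults state the emulated design: 5 colonies x 3 phases at a depth of
    one million reads per library, 10% of genes differentially expressed
    per transition with |log2FC| between 0.5 and 2.5.
    """

    n_genes: int = 2000
    n_colonies: int = 5
    phases: tuple[str, ...] = ("MC", "preTO", "TO")
    library_size: float = 1_000_000.0
    de_fraction: float = 0.1
    log2fc_range: tuple[float, float] = (0.5, 2.5)
    n_go_terms: int = 100
    coherent_term_fraction: float = 0.3
    terms_per_gene: tuple[int, int] = (1, 4)
    baseline_sigma: float = 1.0
    colony_sigma: float = 0.1
    transcripts_per_class: int = 10
    orf_min_aa: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_colonies <= 0:
            raise ValueError("n_genes and n_colonies must be positive")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if len(self.phases) < 2:
            raise ValueError("need at least 2 phases")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.de_fraction * len(self.phases) / 2.0 > 1.0:
            raise ValueError("de_fraction too large for the cyclic design")
        lo, hi = self.log2fc_range
        if lo <= 0 or hi < lo:
            raise ValueError("log2fc_range must be a positive interval")
        if not 0.0 <= self.coherent_term_fraction <= 1.0:
            raise ValueError("coherent_term_fraction must be in [0, 1]")

    @property
    def comparisons(self) -> list[tuple[str, str]]:
        """Cyclic phase comparisons, later phase first: (preTO, MC), (TO, preTO), (MC, TO)."""
        p = self.phases
        return [(p[(i + 1) % len(p)], p[i]) for i in range(len(p))]


@dataclass(frozen=True)
class SyntheticDataset:
    config: SimConfig
    counts: CountExperiment
    truth_de: pd.DataFrame  # gene_id, comparison, status, log2fc
    go_map: pd.DataFrame  # gene_id, go_code, go_name, go_domain
    transcripts: list[TranscriptRecord]
    truth_orf: pd.DataFrame  # transcript_id, true_class
    hit_table: pd.DataFrame  # 13-column outfmt6 + taxon
    truth_taxon: pd.DataFrame  # transcript_id, true_taxon ('' = unassigned)
    theta: pd.Series | None = None  # true baseline relative abundance per gene


def _comparison_label(comparison: tuple[str, str]) -> str:
    return f"{comparison[0]}_vs_{comparison[1]}"


def simulate_experiment(config: SimConfig) -> SyntheticDataset:
    """Generate a full seeded dataset; identical seed gives identical bytes."""
    rng = np.random.default_rng(config.seed)
    n_g, n_c = config.n_genes, config.n_colonies
    phases = list(config.phases)
    n_p = len(phases)
    genes = [f"g{i:05d}" for i in range(n_g)]
    colonies = [f"C{i + 1}" for i in range(n_c)]

    theta = rng.lognormal(mean=0.0, sigma=config.baseline_sigma, size=n_g)
    theta /= theta.sum()

    p_affect = config.de_fraction * n_p / 2.0
    affected = rng.random(n_g) < p_affect
    affected_phase = rng.integers(0, n_p, size=n_g)
    sign = rng.choice([-1.0, 1.0], size=n_g)
    lo, hi = config.log2fc_range
    delta = rng.uniform(lo, hi, size=n_g) * sign
    delta[~affected] = 0.0

    phi = np.zeros((n_g, n_p))
    phi[np.arange(n_g), affected_phase] = delta

    eps = rng.lognormal(mean=0.0, sigma=config.colony_sigma, size=(n_g, n_c))

    sample_rows = []
    columns = {}
    for ci, colony in enumerate(colonies):
        for pi, phase in enumerate(phases):
            sample_id = f"{colony}_{phase}"
            mean = config.library_size * theta * 2.0 ** phi[:, pi] * eps[:, ci]
            columns[sample_id] = rng.poisson(mean)
            sample_rows.append((sample_id, colony, phase))
    counts = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "colony_id", "phase"])
    experiment = CountExperiment(counts=counts, samples=samples)

    truth_rows = []
    for comparison in config.comparisons:
        a, b = comparison
        ia, ib = phases.index(a), phases.index(b)
        lfc = phi[:, ia] - phi[:, ib]
        label = _comparison_label(comparison)
        for gi, gene in enumerate(genes):
            v = lfc[gi]
            status = "null" if v == 0 else ("up" if v > 0 else "down")
            truth_rows.append((gene, label, status, v))
    truth_de = pd.DataFrame(
        truth_rows, columns=["gene_id", "comparison", "status", "log2fc"]
    )

    go_map = _simulate_go_map(config, rng, genes, affected, affected_phase, sign)
    transcripts, truth_orf = simulate_transcripts(config)
    hit_table, truth_taxon = _simulate_hits(config, transcripts, truth_orf)
    return SyntheticDataset(
        config=config,
        counts=experiment,
        truth_de=truth_de,
        go_map=go_map,
        transcripts=transcripts,
        truth_orf=truth_orf,
        hit_table=hit_table,
        truth_taxon=truth_taxon,
        theta=pd.Series(theta, index=genes, name="theta"),
    )


def _simulate_go_map(config, rng, genes, affected, affected_phase, sign):
    """Assign each gene 1-4 GO terms; a coherent term only accepts DE genes
    sharing one (phase, sign) profile, so its DE members always agree in
    direction within every comparison."""
    n_terms = config.n_go_terms
    n_p = len(config.phases)
    codes = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    names = [f"synthetic category {i + 1}" for i in range(n_terms)]
    domains = [GO_DOMAINS[i % len(GO_DOMAINS)] for i in range(n_terms)]
    n_coherent = int(round(config.coherent_term_fraction * n_terms))
    is_coherent = np.zeros(n_terms, dtype=bool)
    is_coherent[:n_coherent] = True
    # profile id = phase_index * 2 + (sign < 0); coherent terms cycle them
    term_profile = np.full(n_terms, -1)
    term_profile[:n_coherent] = np.arange(n_coherent) % (2 * n_p)
    incoherent = np.flatnonzero(~is_coherent)

    lo_t, hi_t = config.terms_per_gene
    rows = []
    used = np.zeros(n_terms, dtype=bool)
    for gi, gene in enumerate(genes):
        k = int(rng.integers(lo_t, hi_t + 1))
        if affected[gi]:
            profile = int(affected_phase[gi]) * 2 + (1 if sign[gi] < 0 else 0)
            pool = np.concatenate(
                [np.flatnonzero(term_profile == profile), incoherent]
            )
        else:
            pool = np.arange(n_terms)
        k = min(k, len(pool))
        chosen = rng.choice(pool, size=k, replace=False)
        for t in chosen:
            used[t] = True
            rows.append((gene, codes[t], names[t], domains[t]))
    # guarantee every term has at least one member gene
    null_genes = np.flatnonzero(~affected)
    for t in np.flatnonzero(~used):
        gi = int(null_genes[int(rng.integers(0, len(null_genes)))]) if len(
            null_genes
        ) else int(rng.integers(0, len(genes)))
        rows.append((genes[gi], codes[t], names[t], domains[t]))
    go_map = pd.DataFrame(rows, columns=["gene_id", "go_code", "go_name", "go_domain"])
    return go_map.sort_values(["gene_id", "go_code"], ignore_index=True)


def _random_codons(rng, n: int) -> str:
    """n random sense codons with a cross-frame blocker every _BLOCK_EVERY."""
    out = []
    taken = 0
    while taken < n:
        chunk = min(_BLOCK_EVERY, n - taken)
        idx = rng.integers(0, len(_SAFE_CODONS), size=chunk)
        out.extend(_SAFE_CODONS[i] for i in idx)
        taken += chunk
        if taken < n:
            out.append(_FRAME_BLOCKER)
            # blocker adds 3 design-frame codons but they are sense codons,
            # so only the shifted frames see stops; not counted toward n
    return "".join(out)


def _build_transcript(rng, true_class: Completeness, min_aa: int) -> str:
    body_len = int(rng.integers(min_aa + 10, 2 * min_aa))
    stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
    if true_class == "complete":
        utr5 = _random_codons(rng, int(rng.integers(5, 15))) + "TAA"
        utr3 = _random_codons(rng, int(rng.integers(5, 15)))
        return utr5 + "ATG" + _random_codons(rng, body_len - 1) + stop + utr3
    if true_class == "open3":
        utr5 = _random_codons(rng, int(rng.integers(5, 15))) + "TAA"
        return utr5 + "ATG" + _random_codons(rng, body_len - 1)
    if true_class == "open5":
        utr3 = _random_codons(rng, int(rng.integers(5, 15)))
        return _random_codons(rng, body_len) + stop + utr3
    if true_class == "open_both":
        return _random_codons(rng, body_len)
    # "none": short sense stretches punctuated by in-frame stops; total codon
    # count stays below min_aa so no frame can hold a long enough open run
    pieces = []
    total = 0
    limit = max(min_aa - 1, 2)
    while total < limit:
        k = int(rng.integers(3, 10))
        k = min(k, limit - total - 1)
        if k <= 0:
            break
        pieces.append(_random_codons(rng, k))
        pieces.append("TAA")
        total += k + 1
    return "".join(pieces) or "TAA"


def simulate_transcripts(
    config: SimConfig,
) -> tuple[list[TranscriptRecord], pd.DataFrame]:
    """Toy transcripts, ``transcripts_per_class`` per completeness class.

    Construction keeps ATG out of every random stretch and caps cross-frame
    open runs with stop-bearing blocker motifs, so the designed class is the
    only candidate the ORF scan can retain at ``orf_min_aa``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    records: list[TranscriptRecord] = []
    truth_rows = []
    i = 0
    for true_class in ORF_CLASSES:
        for _ in range(config.transcripts_per_class):
            seq = _build_transcript(rng, true_class, config.orf_min_aa)
            tid = f"t{i:04d}"
            records.append(TranscriptRecord(transcript_id=tid, sequence=seq))
            truth_rows.append((tid, true_class))
            i += 1
    truth = pd.DataFrame(truth_rows, columns=["transcript_id", "true_class"])
    return records, truth


def _simulate_hits(config, transcripts, truth_orf):
    """Best-hit records for the complete-ORF transcripts, some insignificant."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    complete_ids = truth_orf.loc[
        truth_orf["true_class"] == "complete", "transcript_id"
    ]
    rows = []
    truth_rows = []
    for tid in complete_ids:
        n_hits = int(rng.integers(1, 5))
        best_taxon = ""
        best_key = None
        for h in range(n_hits):
            evalue = 10.0 ** (-float(rng.uniform(0.0, 30.0)))
            bitscore = round(float(rng.uniform(40.0, 400.0)), 1)
            taxon = str(rng.choice(HIT_TAXA, p=HIT_TAXA_WEIGHTS))
            length = int(rng.integers(80, 400))
            rows.append(
                (
                    tid, f"sbj_{tid}_{h}", round(float(rng.uniform(35, 99)), 1),
                    length, int(rng.integers(0, 30)), int(rng.integers(0, 5)),
                    1, length, 1, length, evalue, bitscore, taxon,
                )
            )
            if evalue <= 1e-5:
                key = (evalue, -bitscore)
                if best_key is None or key < best_key:
                    best_key = key
                    best_taxon = taxon
        truth_rows.append((tid, best_taxon))
    hit_table = pd.DataFrame(rows, columns=HIT_TABLE_COLUMNS)
    truth_taxon = pd.DataFrame(truth_rows, columns=["transcript_id", "true_taxon"])
    return hit_table, truth_taxon


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write the six dataset files as TSV/FASTA; returns the file manifest.

    ORF-class truth travels in the FASTA description (``true_class=...``);
    the best-taxon truth is recomputable from the hit table.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "counts": directory / "counts.tsv",
        "samples": directory / "samples.tsv",
        "go_map": directory / "go_map.tsv",
        "truth_de": directory / "truth_de.tsv",
        "transcripts": directory / "transcripts.fasta",
        "hits": directory / "hits.tsv",
    }
    dataset.counts.counts.to_csv(manifest["counts"], sep="\t")
    dataset.counts.samples.to_csv(manifest["samples"], sep="\t", index=False)
    dataset.go_map.to_csv(manifest["go_map"], sep="\t", index=False)
    dataset.truth_de.to_csv(manifest["truth_de"], sep="\t", index=False)
    truth_by_id = dict(
        zip(dataset.truth_orf["transcript_id"], dataset.truth_orf["true_class"])
    )
    with open(manifest["transcripts"], "w") as fh:
        for rec in dataset.transcripts:
            fh.write(f">{rec.transcript_id} true_class={truth_by_id[rec.transcript_id]}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")
    dataset.hit_table.to_csv(manifest["hits"], sep="\t", index=False, header=False)
    return manifest
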