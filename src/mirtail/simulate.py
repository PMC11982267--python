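"""Ground-truth simulators: references, small RNA libraries, qPCR panels, plates.

Everything is driven by a single top-level seed; per-sample random streams are
spawned deterministically from it, so a fixed seed yields byte-identical
outputs.  Sequences are generated in DNA space (T, not U) to match FASTQ
convention.
"""

from __future__ import annotations

import gzip
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .counting import MiRNARecord, ReferenceSet

__all__ = [
    "SampleSpec",
    "SimulationConfig",
    "SimTruth",
    "QpcrDesign",
    "generate_reference",
    "simulate_reads",
    "simulate_qpcr_panel",
    "make_screen_design",
    "simulate_ldh_plate",
    "simulate_luciferase_plate",
    "write_fasta",
    "write_fastq",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    condition: str
    reads: int


@dataclass
class SimulationConfig:
    """Parameters for reference and small RNA library simulation.

    adenylation_prob maps miRNA id (or ``"*"`` as a default for all miRNAs)
    to ``{condition: probability}``.  abundance_weights maps miRNA id to a
    positive sampling weight (uniform when omitted).
    """

    n_mirnas: int
    samples: list[SampleSpec] = field(default_factory=list)
    adenylation_prob: dict[str, dict[str, float]] = field(default_factory=dict)
    length_range: tuple[int, int] = (20, 24)
    abundance_weights: dict[str, float] | None = None
    adapter: str = ""
    read_length: int | None = None  # None = full read-through (insert + adapter)
    error_rate: float = 0.0
    quality_char: str = "I"
    allow_collisions: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_mirnas < 1:
            raise ValueError("n_mirnas must be >= 1")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad length_range {self.length_range}")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        for spec in self.samples:
            if spec.reads <= 0:
                raise ValueError(f"{spec.sample_id}: reads_per_sample must be > 0")
        for mirna, per_cond in self.adenylation_prob.items():
            for cond, p in per_cond.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"adenylation_prob[{mirna}][{cond}]={p} not in [0,1]")
        if self.abundance_weights is not None:
            for mirna, w in self.abundance_weights.items():
                if w <= 0:
                    raise ValueError(f"abundance weight for {mirna} must be > 0")

    def prob_for(self, mirna_id: str, condition: str) -> float:
        per_cond = self.adenylation_prob.get(mirna_id)
        if per_cond is None:
            per_cond = self.adenylation_prob.get("*", {})
        return float(per_cond.get(condition, 0.0))


@dataclass
class SimTruth:
    """Realized (pre-error) per-sample counts and designed qPCR truth."""

    canonical_counts: pd.DataFrame  # rows = miRNA ids, columns = samples
    adenylated_counts: pd.DataFrame
    conditions: dict[str, str]

    def check_totals(self, samples: Sequence[SampleSpec]) -> None:
        total = self.canonical_counts + self.adenylated_counts
        for spec in samples:
            if int(total[spec.sample_id].sum()) != spec.reads:
                raise AssertionError(f"{spec.sample_id}: realized counts != reads")


def generate_reference(config: SimulationConfig, mirna_ids: Sequence[str] | None = None) -> ReferenceSet:
    """Generate ``n_mirnas`` unique random sequences, collision-free by construction.

    No generated sequence equals another, and no sequence equals another
    sequence plus a terminal A (so canonical and +A references never clash),
    unless ``allow_collisions`` disables the rejection step.  Deterministic
    under ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    lo, hi = config.length_range
    if mirna_ids is None:
        mirna_ids = [f"mir-{i + 1:04d}" for i in range(config.n_mirnas)]
    elif len(mirna_ids) != config.n_mirnas:
        raise ValueError("mirna_ids length must equal n_mirnas")
    chosen: list[str] = []
    seen: set[str] = set()
    max_attempts = 1000 * config.n_mirnas + 1000
    attempts = 0
    while len(chosen) < config.n_mirnas:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not draw {config.n_mirnas} collision-free sequences of "
                f"length {lo}-{hi} after {max_attempts} attempts"
            )
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(_BASES[rng.integers(0, 4, size=length)])
        if not config.allow_collisions:
            if seq in seen or (seq + "A") in seen or (seq.endswith("A") and seq[:-1] in seen):
                continue
        elif seq in seen:
            continue
        chosen.append(seq)
        seen.add(seq)
    records = [MiRNARecord(mid, seq) for mid, seq in zip(mirna_ids, chosen)]
    return ReferenceSet.from_records(records)


def simulate_reads(
    refset: ReferenceSet,
    config: SimulationConfig,
) -> tuple[dict[str, list[tuple[str, str]]], SimTruth]:
    """Simulate per-sample small RNA libraries over a reference.

    Each read is a mature sequence or that sequence plus one non-templated
    3' A (Bernoulli with the per-miRNA, per-condition probability); the miRNA
    is drawn multinomially from the abundance weights.  The adapter (if any)
    is appended, the read is cut to ``read_length`` when configured, and
    substitution errors are applied at ``error_rate``.  Returns
    ``{sample_id: [(read_id, sequence), ...]}`` plus the pre-error SimTruth.
    """
    config.validate()
    if not refset.canonical:
        raise ValueError("empty reference")
    if not config.samples:
        raise ValueError("no samples configured")
    known = set(refset.mirna_ids)
    for mirna in config.adenylation_prob:
        if mirna != "*" and mirna not in known:
            raise ValueError(f"adenylation_prob names unknown miRNA {mirna!r}")

    ids = refset.mirna_ids
    seqs = {r.mirna_id: r.sequence for r in refset.canonical}
    if config.abundance_weights is None:
        weights = np.ones(len(ids))
    else:
        missing = set(config.abundance_weights) - known
        if missing:
            raise ValueError(f"abundance_weights names unknown miRNAs {sorted(missing)}")
        weights = np.array([config.abundance_weights.get(m, 1.0) for m in ids])
    probs = weights / weights.sum()

    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(len(config.samples))
    canonical = pd.DataFrame(0, index=ids, columns=[s.sample_id for s in config.samples], dtype=int)
    adenylated = canonical.copy()
    libraries: dict[str, list[tuple[str, str]]] = {}

    for spec, ss in zip(config.samples, streams):
        rng = np.random.default_rng(ss)
        per_mirna = rng.multinomial(spec.reads, probs)
        reads: list[str] = []
        for mid, n in zip(ids, per_mirna):
            if n == 0:
                continue
            p = config.prob_for(mid, spec.condition)
            n_aden = int(rng.binomial(n, p)) if p > 0 else 0
            canonical.loc[mid, spec.sample_id] = n - n_aden
            adenylated.loc[mid, spec.sample_id] = n_aden
            reads.extend([seqs[mid]] * (n - n_aden))
            reads.extend([seqs[mid] + "A"] * n_aden)
        order = rng.permutation(len(reads))
        library: list[tuple[str, str]] = []
        for j, idx in enumerate(order):
            seq = reads[idx]
            if config.adapter:
                full = seq + config.adapter
                seq = full if config.read_length is None else full[: config.read_length]
            if config.error_rate > 0:
                seq = _apply_substitutions(seq, config.error_rate, rng)
            library.append((f"{spec.sample_id}:read{j + 1:07d}", seq))
        libraries[spec.sample_id] = library

    truth = SimTruth(canonical, adenylated, {s.sample_id: s.condition for s in config.samples})
    truth.check_totals(config.samples)
    return libraries, truth


def _apply_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    mask = rng.random(len(arr)) < rate
    if not mask.any():
        return seq
    for i in np.flatnonzero(mask):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


# ---------------------------------------------------------------------------
# qPCR panel simulation


@dataclass
class QpcrDesign:
    """Designed truth for a Ct panel.

    fold holds the true expression of each target in each group relative to
    the control group (control column = 1).  groups maps group label to its
    sample ids.  Ct is generated as ``baseline - log2(expression)`` plus an
    optional per-sample offset (cancelled by internal-control normalization)
    and Gaussian noise.
    """

    fold: pd.DataFrame  # rows = targets, columns = group labels
    groups: dict[str, list[str]]
    control_group: str = "control"
    control_gene: str = "U6"
    baseline_ct: float = 24.0
    control_gene_ct: float = 18.0
    noise_sd: float = 0.0
    sample_offsets: dict[str, float] | None = None

    @property
    def samples(self) -> list[str]:
        return [s for g in self.groups.values() for s in g]

    def design_frame(self) -> pd.DataFrame:
        rows = [(s, g) for g, members in self.groups.items() for s in members]
        return pd.DataFrame(rows, columns=["sample", "group"])


def simulate_qpcr_panel(design: QpcrDesign, seed: int = 0) -> pd.DataFrame:
    """Emit a wide Ct table (rows = targets + internal control, cols = samples)."""
    if (design.fold.values <= 0).any():
        raise ValueError("designed expression folds must be positive")
    if design.control_group not in design.groups:
        raise ValueError(f"control group {design.control_group!r} missing")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    offsets = design.sample_offsets or {}
    columns = {}
    for group, members in design.groups.items():
        folds = design.fold[group]
        for sample in members:
            ct = design.baseline_ct - np.log2(folds.values)
            off = offsets.get(sample, 0.0)
            noise = rng.normal(0.0, design.noise_sd, size=len(ct) + 1) if design.noise_sd > 0 else np.zeros(len(ct) + 1)
            col = np.concatenate([ct + off + noise[:-1], [design.control_gene_ct + off + noise[-1]]])
            columns[sample] = col
    index = list(design.fold.index) + [design.control_gene]
    return pd.DataFrame(columns, index=pd.Index(index, name="target"))


def make_screen_design(
    n_targets: int = 200,
    n_down_restored: int = 20,
    n_down_only: int = 0,
    down_fold: float = 0.25,
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    control_group: str = "control",
    disease_group: str = "disease",
    rescue_group: str = "disease+knockdown",
) -> tuple[QpcrDesign, dict[str, set[str]]]:
    """Design a miRNome panel with a known down-and-restored subset.

    Positives are ``down_fold`` in the disease group and back to 1.0 in the
    rescue group; ``n_down_only`` distractors stay down after rescue; all
    other targets are flat.  Returns the design and the truth sets.
    """
    if n_down_restored + n_down_only > n_targets:
        raise ValueError("designed subsets exceed panel size")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    targets = [f"mir-{i + 1:04d}" for i in range(n_targets)]
    picks = rng.choice(n_targets, size=n_down_restored + n_down_only, replace=False)
    positives = {targets[i] for i in picks[:n_down_restored]}
    down_only = {targets[i] for i in picks[n_down_restored:]}
    fold = pd.DataFrame(
        1.0,
        index=pd.Index(targets, name="target"),
        columns=[control_group, disease_group, rescue_group],
    )
    for t in positives:
        fold.loc[t, disease_group] = down_fold
    for t in down_only:
        fold.loc[t, disease_group] = down_fold
        fold.loc[t, rescue_group] = down_fold
    groups = {
        control_group: [f"ctrl_{i + 1}" for i in range(replicates)],
        disease_group: [f"dis_{i + 1}" for i in range(replicates)],
        rescue_group: [f"kd_{i + 1}" for i in range(replicates)],
    }
    design = QpcrDesign(
        fold=fold, groups=groups, control_group=control_group, noise_sd=noise_sd
    )
    return design, {"down_restored": positives, "down_only": down_only}


# ---------------------------------------------------------------------------
# plate assays


def simulate_ldh_plate(
    true_death: Mapping[str, float],
    total_absorbance: float = 1.2,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired supernatant/attached absorbances with known death fractions."""
    if not true_death:
        raise ValueError("at least one well required")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for well, d in true_death.items():
        if not (0.0 <= d <= 1.0):
            raise ValueError(f"{well}: true death fraction {d} not in [0,1]")
        sup = d * total_absorbance
        att = (1.0 - d) * total_absorbance
        if noise_sd > 0:
            sup = max(sup + rng.normal(0, noise_sd), 0.0)
            att = max(att + rng.normal(0, noise_sd), 0.0)
        rows.append((well, sup, att, d))
    return pd.DataFrame(
        rows, columns=["well", "absorbance_supernatant", "absorbance_attached", "true_death"]
    )


def simulate_luciferase_plate(
    true_ratio: Mapping[str, float],
    renilla: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Firefly/Renilla luminescence pairs with known true ratios."""
    if not true_ratio:
        raise ValueError("at least one well required")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for well, r in true_ratio.items():
        if r < 0:
            raise ValueError(f"{well}: negative ratio")
        fire = r * renilla
        ren = renilla
        if noise_sd > 0:
            fire = max(fire + rng.normal(0, noise_sd), 0.0)
            ren = max(ren + rng.normal(0, noise_sd), 1e-9)
        rows.append((well, fire, ren, r))
    return pd.DataFrame(rows, columns=["well", "firefly", "renilla", "true_ratio"])


# ---------------------------------------------------------------------------
# deterministic writers


def write_fasta(refset: ReferenceSet, path: str | Path, which: str = "canonical") -> None:
    records = getattr(refset, which)
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.mirna_id}\n{rec.sequence}\n")


def write_fastq(
    reads: Sequence[tuple[str, str]],
    path: str | Path,
    quality_char: str = "I",
) -> None:
    path = Path(path)
    text = "".join(
        f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n" for read_id, seq in reads
    )
    if path.suffix == ".gz":
        # fixed mtime and blank embedded name keep gzip bytes run-independent
        with open(path, "wb") as raw, gzip.GzipFile(
            filename="", mode="wb", fileobj=raw, mtime=0
        ) as out:
            out.write(text.encode())
    else:
        path.write_text(text)
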