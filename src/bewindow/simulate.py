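"""Truth-known simulation of base-editing amplicon experiments.

The generator emulates the statistical structure of amplicon deep sequencing
of base-edited loci: a window-shaped per-position conversion probability
over the protospacer (peaking in the editor's on-target window, with low
bystander tails), an inhibitor (treated) condition that attenuates editing
per position, low-rate small indels inside the protospacer, and
Illumina-like overlapping read pairs with per-base miscalls and Phred
quality strings.  Every sample carries its generative truth (per-position
frequencies, allele pool, outcome-class fractions), so each pipeline stage
has an exact oracle.  All randomness derives from a single integer seed.

Per-position edits are independent by default; ``coedit_correlation``
introduces positive co-editing through a shared per-read uniform latent
(with probability rho a position reuses the read's shared draw), which
preserves each position's marginal probability exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .demo import demo_abe_target, demo_cbe_target
from .quantify import EditingProfile
from .targets import (AmpliconTarget, PROTOSPACER_LEN, to_amplicon_coord,
                      revcomp)

__all__ = ["SimulationConfig", "SimulatedPool", "simulate_allele_pool",
           "pool_to_fastq", "scenario_presets", "truth_selectivity_fold",
           "zero_noise"]

MIN_OVERLAP_GUARD = 11
_CONDITION_CODE = {"control": 0, "treated": 1}


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Generative truth for one simulated amplicon experiment.

    ``edit_prob`` maps editable protospacer positions to the per-read
    conversion probability in the control condition; ``inhibition`` maps
    positions to the inhibition rate IR applied in the treated condition
    (treated probability = control probability * (1 - IR)).
    """

    target: AmpliconTarget
    edit_prob: dict
    inhibition: dict = field(default_factory=dict)
    coedit_correlation: float = 0.0
    indel_rate: float = 0.0
    indel_length_probs: dict = field(
        default_factory=lambda: {1: 0.6, 2: 0.3, 3: 0.1})
    seq_error_rate: float = 0.002
    qual_mean: float = 35.0
    qual_sd: float = 4.0
    read_length: int = 100
    coverage: int = 2000
    seed: int = 0

    def __post_init__(self):
        editable = set(self.target.editable_positions())
        bad = set(self.edit_prob) - editable
        if bad:
            raise SimulationConfigError(
                f"edit_prob positions {sorted(bad)} are not editable "
                f"({self.target.substrate_base} on the protospacer strand)")
        for d, label in ((self.edit_prob, "edit_prob"), (self.inhibition, "inhibition")):
            for p, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise SimulationConfigError(f"{label}[{p}]={v} outside [0, 1]")
        if not 0.0 <= self.coedit_correlation < 1.0:
            raise SimulationConfigError("coedit_correlation must be in [0, 1)")
        for rate in (self.indel_rate, self.seq_error_rate):
            if not 0.0 <= rate <= 1.0:
                raise SimulationConfigError("rates must be in [0, 1]")
        if abs(sum(self.indel_length_probs.values()) - 1.0) > 1e-9:
            raise SimulationConfigError("indel_length_probs must sum to 1")
        amp_len = len(self.target.amplicon_seq)
        if 2 * self.read_length - amp_len < MIN_OVERLAP_GUARD:
            raise SimulationConfigError(
                f"2 * read_length must exceed the amplicon length by >= "
                f"{MIN_OVERLAP_GUARD} so pairs overlap mergeably")

    def effective_probs(self, condition: str) -> dict:
        if condition not in _CONDITION_CODE:
            raise SimulationConfigError(f"condition must be control/treated, got {condition!r}")
        if condition == "control":
            return dict(self.edit_prob)
        return {p: prob * (1.0 - self.inhibition.get(p, 0.0))
                for p, prob in self.edit_prob.items()}


def zero_noise(config: SimulationConfig) -> SimulationConfig:
    """The same experiment in the zero-noise regime.

    No sequencing miscalls, no indels, and constant base quality 35 (random
    sub-30 qualities would mask random bases, which is sampling noise rather
    than pipeline error).
    """
    return dataclasses.replace(config, seq_error_rate=0.0, indel_rate=0.0,
                               qual_sd=0.0)


@dataclass
class SimulatedPool:
    """Realized allele pool with its generative truth."""

    condition: str
    alleles: list              # [(sequence, count)] sorted by count desc
    n_reads: int
    configured_freqs: np.ndarray   # (20,) marginal conversion probs, NaN if N/A
    realized_freqs: np.ndarray     # (20,) empirical, deletion-excluded denominators
    realized_denoms: np.ndarray    # (20,)
    class_fractions: dict          # realized {perfect, unedited, imperfect_edit, indel_allele}
    expected_class_fractions: dict  # closed-form (independent edits) or None
    target: AmpliconTarget
    seed: int

    def realized_profile(self, label: str = "", replicate: int = 0) -> EditingProfile:
        return EditingProfile(self.target.editor, self.realized_freqs.copy(),
                              self.realized_denoms.copy(), label, replicate)

    def configured_profile(self, label: str = "", replicate: int = 0) -> EditingProfile:
        denoms = np.where(np.isnan(self.configured_freqs), 0, self.n_reads)
        return EditingProfile(self.target.editor, self.configured_freqs.copy(),
                              denoms.astype(np.int64), label, replicate)

    def truth_json(self) -> str:
        payload = {
            "condition": self.condition,
            "n_reads": self.n_reads,
            "seed": self.seed,
            "configured_freqs": [None if np.isnan(f) else float(f)
                                 for f in self.configured_freqs],
            "realized_freqs": [None if np.isnan(f) else float(f)
                               for f in self.realized_freqs],
            "class_fractions": self.class_fractions,
            "expected_class_fractions": self.expected_class_fractions,
            "n_distinct_alleles": len(self.alleles),
        }
        return json.dumps(payload, indent=2)


def _expected_class_fractions(config: SimulationConfig, probs: dict):
    if config.coedit_correlation > 0:
        return None
    intended = set(config.target.intended_positions)
    keep = 1.0 - config.indel_rate
    unedited = keep * float(np.prod([1.0 - v for v in probs.values()]))
    perfect = 0.0
    if intended:
        perfect = keep
        for p, v in probs.items():
            perfect *= v if p in intended else (1.0 - v)
        if not intended <= set(probs):
            perfect = 0.0
    imperfect = keep - unedited - perfect
    return {"perfect": perfect, "unedited": unedited,
            "imperfect_edit": imperfect, "indel_allele": config.indel_rate}


def simulate_allele_pool(config: SimulationConfig,
                         condition: str = "control") -> SimulatedPool:
    """Draw ``coverage`` allele realisations and their exact truth tables."""
    probs = config.effective_probs(condition)
    target = config.target
    rng = np.random.default_rng([config.seed, _CONDITION_CODE[condition], 7])
    n = config.coverage
    positions = sorted(probs)
    k = len(positions)
    pvec = np.array([probs[p] for p in positions])

    if k:
        shared = rng.random(n)
        use_shared = rng.random((n, k)) < config.coedit_correlation
        u = np.where(use_shared, shared[:, None], rng.random((n, k)))
        edited = u < pvec[None, :]
    else:
        edited = np.zeros((n, 0), dtype=bool)

    has_indel = rng.random(n) < config.indel_rate
    indel_is_del = rng.random(n) < 0.5
    lengths = np.array(sorted(config.indel_length_probs))
    lprobs = np.array([config.indel_length_probs[l] for l in lengths])
    indel_len = rng.choice(lengths, size=n, p=lprobs)
    indel_pos = rng.integers(1, PROTOSPACER_LEN + 1, size=n)
    ins_bases = rng.integers(0, 4, size=(n, int(lengths.max()) if len(lengths) else 1))

    amp = target.amplicon_seq
    minus = target.protospacer_strand == "-"
    sub_product = target.product_base if not minus else revcomp(target.product_base)
    offsets = {p: to_amplicon_coord(target, p) for p in range(1, PROTOSPACER_LEN + 1)}
    intended = set(target.intended_positions)
    bases = "ACGT"

    allele_counts = {}
    class_counts = {"perfect": 0, "unedited": 0, "imperfect_edit": 0,
                    "indel_allele": 0}
    conv_num = np.zeros(PROTOSPACER_LEN, dtype=np.int64)
    conv_den = np.zeros(PROTOSPACER_LEN, dtype=np.int64)

    for i in range(n):
        edits = {positions[j] for j in range(k) if edited[i, j]}
        seq = list(amp)
        for p in edits:
            seq[offsets[p]] = sub_product
        deleted_positions = set()
        if has_indel[i]:
            length = int(indel_len[i])
            p0 = int(indel_pos[i])
            if indel_is_del[i]:
                span = [p for p in range(p0, min(p0 + length, PROTOSPACER_LEN + 1))]
                offs = sorted(offsets[p] for p in span)
                for o in reversed(offs):
                    seq[o] = ""
                deleted_positions = set(span)
            else:
                insert = "".join(bases[b] for b in ins_bases[i, :length])
                anchor = offsets[p0]
                seq[anchor] = insert + seq[anchor]
        allele = "".join(seq)
        allele_counts[allele] = allele_counts.get(allele, 0) + 1

        if has_indel[i]:
            cls = "indel_allele"
        elif not edits:
            cls = "unedited"
        elif edits == intended:
            cls = "perfect"
        else:
            cls = "imperfect_edit"
        class_counts[cls] += 1

        for p in positions:
            if p in deleted_positions:
                continue
            conv_den[p - 1] += 1
            conv_num[p - 1] += p in edits

    configured = np.full(PROTOSPACER_LEN, np.nan)
    for p in target.editable_positions():
        configured[p - 1] = probs.get(p, 0.0)
    realized = np.full(PROTOSPACER_LEN, np.nan)
    denoms = np.zeros(PROTOSPACER_LEN, dtype=np.int64)
    for p in target.editable_positions():
        if p in probs:
            denoms[p - 1] = conv_den[p - 1]
            if conv_den[p - 1] > 0:
                realized[p - 1] = conv_num[p - 1] / conv_den[p - 1]
        else:
            # never-edited positions: denominator is every read without a
            # deletion there; realized frequency is exactly zero
            denoms[p - 1] = n
            realized[p - 1] = 0.0

    alleles = sorted(allele_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    fractions = {c: cnt / n for c, cnt in class_counts.items()}
    return SimulatedPool(condition, alleles, n, configured, realized, denoms,
                         fractions, _expected_class_fractions(config, probs),
                         target, config.seed)


def _qual_string(q: np.ndarray) -> str:
    return (q.astype(np.uint8) + 33).tobytes().decode("ascii")


def pool_to_fastq(pool: SimulatedPool, config: SimulationConfig,
                  path_r1, path_r2):
    """Emit the pool as a paired FASTQ sample (R1/R2), deterministic under seed."""
    rng = np.random.default_rng([config.seed, _CONDITION_CODE[pool.condition], 13])
    rl = config.read_length
    base_arr = np.frombuffer(b"ACGT", dtype=np.uint8)
    base_index = np.zeros(256, dtype=np.int64)
    for j, b in enumerate(base_arr):
        base_index[b] = j

    def make_read(frag: str):
        L = min(rl, len(frag))
        arr = np.frombuffer(frag[:L].encode("ascii"), dtype=np.uint8).copy()
        if config.seq_error_rate > 0:
            errs = np.flatnonzero(rng.random(L) < config.seq_error_rate)
            if len(errs):
                # substitute with one of the three other bases
                shift = rng.integers(1, 4, size=len(errs))
                arr[errs] = base_arr[(base_index[arr[errs]] + shift) % 4]
        qual = np.clip(np.rint(rng.normal(config.qual_mean, config.qual_sd, L)),
                       2, 41).astype(np.int16)
        return arr.tobytes().decode("ascii"), qual

    i = 0
    with open(path_r1, "w") as h1, open(path_r2, "w") as h2:
        for allele, count in pool.alleles:
            if len(allele) < MIN_OVERLAP_GUARD:
                raise SimulationConfigError(
                    "allele shorter than the minimum mergeable fragment")
            rc = revcomp(allele)
            for _ in range(count):
                s1, q1 = make_read(allele)
                s2, q2 = make_read(rc)
                h1.write(f"@sim{i}/1\n{s1}\n+\n{_qual_string(q1)}\n")
                h2.write(f"@sim{i}/2\n{s2}\n+\n{_qual_string(q2)}\n")
                i += 1


def truth_selectivity_fold(config: SimulationConfig, partition) -> float:
    """Construction-truth selectivity fold: mean IR out-of-window / mean IR on-target.

    Averages the configured inhibition rates over the positions that carry
    editing in the control condition (the positions where IR is observable).
    """
    on = [config.inhibition.get(p, 0.0) for p in sorted(partition.on_target)
          if config.edit_prob.get(p, 0.0) > 0]
    out = [config.inhibition.get(p, 0.0) for p in sorted(partition.out_of_window)
           if config.edit_prob.get(p, 0.0) > 0]
    if not on or not out or np.mean(on) == 0:
        return float("nan")
    return float(np.mean(out) / np.mean(on))


def scenario_presets() -> dict:
    """Named, seeded configurations emulating the studied experiment shapes.

    ``broad-window-cbe``
        A3A-like CBE: strong editing across the 4-8 window with appreciable
        bystander tails at out-of-window cytidines; no inhibitor.
    ``focused-inhibitor``
        The same editor plus an inhibitor condition attenuating out-of-window
        editing far more than on-target editing (IR 0.9 vs 0.1; construction
        selectivity fold 9.0).
    ``abe``
        ABE7.10-like editor with its narrower 4-7 window; no inhibitor.
    """
    cbe = demo_cbe_target(intended_positions=(4,))
    abe = demo_abe_target(intended_positions=(5,))
    window_cbe = {4: 0.50, 5: 0.45, 7: 0.50, 8: 0.40}
    tails_cbe = {1: 0.15, 11: 0.12, 15: 0.10, 18: 0.08}
    presets = {
        "broad-window-cbe": SimulationConfig(
            target=cbe, edit_prob={**window_cbe, **tails_cbe},
            indel_rate=0.01, coverage=2000, seed=11),
        "focused-inhibitor": SimulationConfig(
            target=cbe, edit_prob={**window_cbe, **tails_cbe},
            inhibition={**{p: 0.1 for p in window_cbe},
                        **{p: 0.9 for p in tails_cbe}},
            indel_rate=0.01, coverage=2000, seed=12),
        "abe": SimulationConfig(
            target=abe,
            edit_prob={4: 0.45, 5: 0.50, 6: 0.40, 7: 0.45,
                       2: 0.10, 10: 0.08, 13: 0.12, 17: 0.09},
            indel_rate=0.005, coverage=2000, seed=13),
    }
    return presets
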