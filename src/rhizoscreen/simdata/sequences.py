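"""Synthetic 16S sequence families with planted ASV-to-isolate divergence.

Each simulated isolate gets a random full-length 16S-like sequence from
which four "database" regions are cut, mirroring how a culture collection
is typically sequenced: a near-start single read (27F), the V4 window in
forward (515F) and reverse-complement (515R) orientation, and the merged
paired-read V4 product (identical in span to 515F).

A configurable fraction of ASVs is derived from the V4 window of a chosen
isolate by substituting an exact number of sites, ``round(rate * length)``,
so the percent identity of each planted pair is known in closed form.
The remaining ASVs are i.i.d. uniform DNA and act as the unmatchable
negative class.  No indels are introduced and substitutions are kept away
from the read ends and from each other (see ``MUTATION_MARGIN``): the
downstream matcher is ungapped and trims terminal mismatch runs, so the
planted truth must stay on one full-length diagonal to remain observable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
# IUPAC ambiguity complements, needed when references carry ambiguity codes
_COMPLEMENT.update(
    {"R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
     "B": "V", "V": "B", "D": "H", "H": "D"}
)

#: canonical V4 start coordinate on a full-length 16S gene; clipped to fit
#: shorter simulated genes
V4_CANONICAL_START = 515


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes supported)."""
    return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))


@dataclass(frozen=True)
class SequenceSimConfig:
    """Configuration for the 16S family simulator.

    Parameters
    ----------
    seed
        RNG seed; identical seeds reproduce byte-identical output.
    n_isolates, n_asvs
        Number of culture-collection isolates and of ASVs to emit.
    full_length
        Length (nt) of each simulated full 16S gene.
    v4_length
        Length (nt) of the V4 window (the merged/515F/515R region and of
        every ASV).
    read_length_27f
        Length (nt) of the near-start 27F read.
    divergence_range
        ``(low, high)`` per-site substitution probabilities for planted
        ASVs; each matchable ASV draws its rate uniformly from this range.
        Rates above 0.10 are rejected — they leave the >=95% identity
        regime the matcher is meant for.
    fraction_matchable
        Fraction of ASVs derived from an isolate; the rest are random DNA.
    """

    seed: int = 0
    n_isolates: int = 63
    n_asvs: int = 100
    full_length: int = 1200
    v4_length: int = 253
    read_length_27f: int = 250
    divergence_range: tuple[float, float] = (0.0, 0.048)
    fraction_matchable: float = 0.87

    def __post_init__(self) -> None:
        if self.n_isolates < 1 or self.n_asvs < 0:
            raise ValueError("n_isolates must be >= 1 and n_asvs >= 0")
        if self.v4_length + self.read_length_27f > self.full_length:
            raise ValueError("v4_length + read_length_27f must be <= full_length")
        lo, hi = self.divergence_range
        if not (0.0 <= lo <= hi):
            raise ValueError("divergence_range must satisfy 0 <= low <= high")
        if hi > 0.10:
            raise ValueError(
                "divergence above 0.10 is outside the supported "
                ">=95% identity regime"
            )
        if not 0.0 <= self.fraction_matchable <= 1.0:
            raise ValueError("fraction_matchable must be in [0, 1]")

    @property
    def v4_start(self) -> int:
        """Start offset of the V4 window on the full-length gene."""
        return max(self.read_length_27f,
                   min(V4_CANONICAL_START, self.full_length - self.v4_length))


@dataclass
class SequenceSimResult:
    """Output bundle of :func:`simulate_sequences`.

    Attributes
    ----------
    asvs
        ``{asv_id: sequence}`` of V4-length ASVs.
    regions
        ``{region: {isolate_id: sequence}}`` for the four reference
        regions (``merged``, ``27F``, ``515F``, ``515R``).
    full_length
        ``{isolate_id: sequence}`` full genes (for invariant checks).
    truth
        Per-ASV table with columns ``asv_id``, ``source_isolate``
        (empty string for unrelated ASVs), ``planted_divergence``,
        ``n_substitutions`` and ``expected_percent_identity``.
    """

    asvs: dict[str, str]
    regions: dict[str, dict[str, str]]
    full_length: dict[str, str]
    truth: pd.DataFrame

    def write_fasta(self, outdir: str | Path) -> dict[str, Path]:
        """Write one FASTA per region plus one for the ASVs; return paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        asv_path = outdir / "asvs.fasta"
        with asv_path.open("w") as fh:
            for name, seq in self.asvs.items():
                fh.write(f">{name}\n{seq}\n")
        paths["asvs"] = asv_path
        for region, entries in self.regions.items():
            p = outdir / f"refs_{region}.fasta"
            with p.open("w") as fh:
                for isolate, seq in entries.items():
                    fh.write(f">{isolate}|{region} region={region} "
                             f"isolate={isolate}\n{seq}\n")
            paths[region] = p
        return paths


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return BASES[rng.integers(0, 4, size=length)].tobytes().decode()


#: substitutions are planted at least this far from either read end and
#: from each other.  A maximum-score ungapped local alignment trims a
#: terminal mismatch run whenever the run's prefix scores negatively; with
#: a 3-nt margin and 3-nt spacing every prefix through the m-th planted
#: mismatch spans >= 3m+1 sites, which scores positively under any
#: reward/|penalty| ratio >= 2/3 x 3 — so the full-length diagonal stays
#: the strict optimum and the planted identity remains observable.
MUTATION_MARGIN = 3
MUTATION_SPACING = 3


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    """Substitute exactly ``round(rate * len)`` well-separated sites."""
    length = len(seq)
    n_sub = int(round(rate * length))
    if n_sub == 0:
        return seq, 0
    candidates = rng.permutation(np.arange(MUTATION_MARGIN,
                                           length - MUTATION_MARGIN))
    positions: list[int] = []
    for pos in candidates:
        if all(abs(pos - p) >= MUTATION_SPACING for p in positions):
            positions.append(int(pos))
            if len(positions) == n_sub:
                break
    if len(positions) < n_sub:
        raise ValueError(
            f"cannot place {n_sub} spaced substitutions on a "
            f"{length}-nt sequence")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for pos in positions:
        choices = BASES[BASES != arr[pos]]
        arr[pos] = rng.choice(choices)
    return arr.tobytes().decode(), n_sub


def simulate_sequences(config: SequenceSimConfig) -> SequenceSimResult:
    """Simulate a culture collection and an ASV set with known provenance.

    The first ``round(fraction_matchable * n_asvs)`` ASVs are planted from
    cyclically assigned source isolates; the rest are unrelated uniform DNA.
    Truth records the realized substitution count, so
    ``expected_percent_identity`` equals the Hamming identity of the
    emitted pair exactly.
    """
    rng = np.random.default_rng(config.seed)
    v4_start = config.v4_start
    v4_end = v4_start + config.v4_length

    full: dict[str, str] = {}
    regions: dict[str, dict[str, str]] = {r: {} for r in
                                          ("merged", "27F", "515F", "515R")}
    isolate_ids = [f"iso{i + 1:03d}" for i in range(config.n_isolates)]
    for iso in isolate_ids:
        gene = _random_dna(rng, config.full_length)
        full[iso] = gene
        v4 = gene[v4_start:v4_end]
        regions["merged"][iso] = v4
        regions["27F"][iso] = gene[: config.read_length_27f]
        regions["515F"][iso] = v4
        regions["515R"][iso] = reverse_complement(v4)

    n_matchable = int(round(config.fraction_matchable * config.n_asvs))
    lo, hi = config.divergence_range
    asvs: dict[str, str] = {}
    rows = []
    for j in range(config.n_asvs):
        asv_id = f"asv{j + 1:04d}"
        if j < n_matchable:
            iso = isolate_ids[j % config.n_isolates]
            rate = rng.uniform(lo, hi) if hi > lo else lo
            seq, n_sub = _mutate(rng, regions["merged"][iso], rate)
            identity = 100.0 * (1.0 - n_sub / len(seq))
            rows.append((asv_id, iso, rate, n_sub, identity))
        else:
            seq = _random_dna(rng, config.v4_length)
            rows.append((asv_id, "", np.nan, -1, np.nan))
        asvs[asv_id] = seq

    truth = pd.DataFrame(
        rows,
        columns=["asv_id", "source_isolate", "planted_divergence",
                 "n_substitutions", "expected_percent_identity"],
    )
    return SequenceSimResult(asvs=asvs, regions=regions, full_length=full,
                             truth=truth)
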