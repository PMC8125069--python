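"""Position-specific scoring models for effector-associated protein motifs.

Domain discovery in this pipeline (Rhs core repeats, the VgrG spike, PAAR,
SpvB/TcdB N-termini, T9SS type-A sorting domains, hemagglutinin repeats,
signal peptides) runs on PSSMs built from seed alignments rather than on
profile HMMs.  The planted motif cores this package targets are ungapped, so
a gapless log-odds scan gives the same detector contract — protein in,
scored spans out — without an external inference engine.  Thresholds are
calibrated empirically from shuffled-sequence decoys at a requested
false-positive rate, and that calibration is recorded with the model.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .genome_io import ProteinRecord

logger = logging.getLogger(__name__)

__all__ = [
    "MotifModel",
    "DomainHit",
    "build_pssm",
    "scan_protein",
    "calibrate_threshold",
    "load_motif_library",
    "MANDATORY_MOTIFS",
]

#: column order of every PSSM
RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_RES_IDX = {c: i for i, c in enumerate(RESIDUES)}
_GAP_CHARS = {"-", ".", "*"}

#: motifs the pipeline cannot run without
MANDATORY_MOTIFS = ("rhs_core", "vgrg")


class MotifBuildError(ValueError):
    """Raised for unusable seed alignments."""


class MotifConfigError(ValueError):
    """Raised for an invalid motif-library configuration."""


class CalibrationError(ValueError):
    """Raised when decoy calibration cannot be performed."""


@dataclass
class MotifModel:
    """Log-odds scoring matrix for one ungapped motif.

    ``scores`` has shape (width, 20) in bits, columns ordered as
    :data:`RESIDUES`; residue X (and any non-standard residue) scores 0.
    """

    name: str
    width: int
    scores: np.ndarray
    background: np.ndarray
    bit_threshold: float = 0.0
    source_alignment: str | None = None
    calibration: dict | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.width < 5:
            raise MotifBuildError(f"motif {self.name}: width {self.width} < 5")
        if self.scores.shape != (self.width, 20):
            raise MotifBuildError(f"motif {self.name}: bad score shape")
        if not np.all(np.isfinite(self.scores)):
            raise MotifBuildError(f"motif {self.name}: non-finite scores")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise MotifBuildError(
                f"motif {self.name}: background does not sum to 1")

    @property
    def max_score(self) -> float:
        return float(self.scores.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(RESIDUES[i] for i in self.scores.argmax(axis=1))


@dataclass(frozen=True)
class DomainHit:
    """One motif match on a protein (1-based inclusive span, bits)."""

    protein_id: str
    motif_name: str
    start: int
    end: int
    score: float

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad hit span {self.start}..{self.end}")


def _encode_for_pssm(seq: str) -> np.ndarray:
    """Map residues to PSSM columns; X/non-standard map to 20 (scores 0)."""
    return np.array([_RES_IDX.get(c, 20) for c in seq.upper()],
                    dtype=np.intp)


def build_pssm(seed_alignment, pseudocount: float = 1.0,
               background: np.ndarray | None = None,
               name: str = "motif",
               source_alignment: str | None = None) -> MotifModel:
    """Build a log-odds PSSM from an aligned set of protein sequences.

    ``seed_alignment`` is a list of equal-length aligned strings (or
    ``(id, string)`` pairs).  Columns with more than 50 % gap characters are
    dropped.  Per retained column ``c`` and residue ``r``::

        score(c, r) = log2((count(c, r) + pc * bg(r)) / ((n_c + pc) * bg(r)))

    where ``n_c`` is the number of non-gap residues in the column and ``pc``
    the pseudocount.
    """
    seqs = [s[1] if isinstance(s, tuple) else getattr(s, "sequence", s)
            for s in seed_alignment]
    if len(seqs) < 2:
        raise MotifBuildError(f"motif {name}: need >= 2 seed sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise MotifBuildError(f"motif {name}: ragged seed alignment")
    if pseudocount <= 0:
        raise MotifBuildError(f"motif {name}: pseudocount must be > 0")
    if background is None:
        background = np.full(20, 1 / 20)
    background = np.asarray(background, dtype=float)

    kept_scores = []
    n = len(seqs)
    for c in range(L):
        col = [s[c].upper() for s in seqs]
        gaps = sum(ch in _GAP_CHARS for ch in col)
        if gaps > 0.5 * n:
            continue
        counts = np.zeros(20)
        for ch in col:
            if ch in _RES_IDX:
                counts[_RES_IDX[ch]] += 1
        n_c = counts.sum()
        scores = np.log2((counts + pseudocount * background)
                         / ((n_c + pseudocount) * background))
        kept_scores.append(scores)
    if not kept_scores:
        raise MotifBuildError(f"motif {name}: all columns gapped")
    return MotifModel(name, len(kept_scores), np.vstack(kept_scores),
                      background, source_alignment=source_alignment)


def _window_scores(model: MotifModel, seq: str) -> np.ndarray:
    """Score of every offset's gapless window; empty if protein too short."""
    idx = _encode_for_pssm(seq)
    W = model.width
    if idx.size < W:
        return np.empty(0)
    # 21st column of zeros absorbs X / non-standard residues
    padded = np.hstack([model.scores, np.zeros((W, 1))])
    windows = np.lib.stride_tricks.sliding_window_view(idx, W)
    return padded[np.arange(W), windows].sum(axis=1)


def scan_protein(model: MotifModel, protein: ProteinRecord | str,
                 threshold: float | None = None) -> list[DomainHit]:
    """Scan a protein with gapless windows; report merged above-threshold hits.

    Overlapping qualifying windows merge into a single hit that keeps the
    maximal-scoring window's span and score.  Hits are sorted by start.
    """
    if isinstance(protein, str):
        pid, seq = "protein", protein
    else:
        pid, seq = protein.id, protein.sequence
    if threshold is None:
        threshold = model.bit_threshold
    scores = _window_scores(model, seq)
    if scores.size == 0:
        return []
    offsets = np.nonzero(scores >= threshold)[0]
    if offsets.size == 0:
        return []
    W = model.width
    hits: list[DomainHit] = []
    run = [offsets[0]]
    for off in offsets[1:]:
        if off <= run[-1] + W - 1:  # windows overlap
            run.append(off)
        else:
            hits.append(_best_window_hit(pid, model, scores, run))
            run = [off]
    hits.append(_best_window_hit(pid, model, scores, run))
    return hits


def _best_window_hit(pid: str, model: MotifModel, scores: np.ndarray,
                     run: list[int]) -> DomainHit:
    best = max(run, key=lambda o: (scores[o], -o))
    return DomainHit(pid, model.name, int(best) + 1,
                     int(best) + model.width, float(scores[best]))


def best_window_score(model: MotifModel, seq: str) -> float:
    """Maximum single-window score on a sequence (-inf if too short)."""
    scores = _window_scores(model, seq)
    return float(scores.max()) if scores.size else -math.inf


def calibrate_threshold(model: MotifModel, decoys: list[str],
                        target_fpr: float = 0.001) -> float:
    """Set the smallest bit threshold keeping the decoy hit rate <= target.

    ``decoys`` are typically residue-shuffled copies of the true-positive
    seeds.  The returned value is stored on ``model.bit_threshold``.
    """
    if len(decoys) < 100:
        raise CalibrationError(
            f"motif {model.name}: need >= 100 decoys, got {len(decoys)}")
    if not 0 < target_fpr <= 1:
        raise CalibrationError("target_fpr must be in (0, 1]")
    best = np.array([best_window_score(model, d) for d in decoys])
    best = best[np.isfinite(best)]
    if best.size == 0:
        raise CalibrationError(
            f"motif {model.name}: every decoy shorter than the motif")
    allowed = math.floor(target_fpr * best.size)
    ordered = np.sort(best)  # ascending
    # smallest candidate threshold with #(best >= t) <= allowed
    threshold = None
    for t in np.unique(ordered):
        firing = best.size - np.searchsorted(ordered, t, side="left")
        if firing <= allowed:
            threshold = float(t)
            break
    if threshold is None:
        threshold = float(np.nextafter(ordered[-1], np.inf))
    model.bit_threshold = threshold
    model.calibration = {
        "method": "decoy_fpr",
        "target_fpr": target_fpr,
        "n_decoys": int(best.size),
        "decoy_firing": int((best >= threshold).sum()),
    }
    return threshold


def shuffle_sequence(seq: str, rng: np.random.Generator) -> str:
    chars = np.array(list(seq))
    rng.shuffle(chars)
    return "".join(chars)


def make_decoy(seed_seq: str, rng: np.random.Generator,
               decoy_length: int = 1000) -> str:
    """A residue-shuffled seed embedded in background-composition sequence.

    Padding the shuffle out to a realistic protein length matters: a scan
    threshold must control the false-positive rate per *protein*, and a
    protein exposes hundreds of windows, not one.
    """
    core = shuffle_sequence(seed_seq, rng)
    pad = max(0, decoy_length - len(core))
    left = int(rng.integers(0, pad + 1))
    residues = np.array(list(RESIDUES))
    return ("".join(rng.choice(residues, size=left)) + core
            + "".join(rng.choice(residues, size=pad - left)))


def _read_aligned_fasta(path: Path) -> list[tuple[str, str]]:
    recs = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not recs:
        raise MotifBuildError(f"empty seed alignment {path}")
    return recs


def load_motif_library(config: dict, base_dir: str | Path | None = None,
                       seed: int = 0) -> dict[str, MotifModel]:
    """Build and calibrate every motif model named in ``config``.

    ``config`` maps motif name -> entry with keys ``path`` (aligned FASTA),
    and either ``bits`` for a fixed threshold or ``fpr`` (+ optional
    ``n_decoys``, default 1000, and ``decoy_length``, default 1000) for
    decoy calibration.  The working threshold follows a two-point rule in
    the spirit of profile noise/trusted cutoffs: the decoy calibration
    gives the noise floor, the weakest seed's self-score gives the trusted
    ceiling, and the threshold sits ``threshold_fraction`` (default 1/3)
    of the way up — far above the null tail yet well below every true
    carrier.  Entries may also be given as a list of ``(name, entry)``
    pairs, in which case duplicate names are a configuration error.
    Missing optional motifs are logged and skipped; missing mandatory
    motifs (rhs_core, vgrg) abort.
    """
    if not isinstance(config, dict):
        items = list(config)
        names = [n for n, _ in items]
        if len(set(names)) != len(names):
            raise MotifConfigError("duplicate motif name in library config")
        config = dict(items)
    base = Path(base_dir) if base_dir else None
    library: dict[str, MotifModel] = {}
    for name, entry in config.items():
        path = Path(entry["path"])
        if base and not path.is_absolute():
            path = base / path
        if not path.exists():
            if name in MANDATORY_MOTIFS:
                raise MotifConfigError(
                    f"mandatory motif {name}: missing seed alignment {path}")
            logger.warning("optional motif %s: missing %s; skipped",
                           name, path)
            continue
        seeds = _read_aligned_fasta(path)
        model = build_pssm(seeds, pseudocount=float(entry.get("pseudocount", 1.0)),
                           name=name, source_alignment=str(path))
        if "bits" in entry:
            model.bit_threshold = float(entry["bits"])
            model.calibration = {"method": "fixed"}
        else:
            fpr = float(entry.get("fpr", 0.001))
            n_decoys = int(entry.get("n_decoys", 1000))
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, zlib.crc32(name.encode())]))
            ungapped = [s.replace("-", "").replace(".", "")
                        for _, s in seeds]
            decoy_length = int(entry.get("decoy_length", 1000))
            decoys = [make_decoy(ungapped[i % len(ungapped)], rng,
                                 decoy_length)
                      for i in range(n_decoys)]
            noise = calibrate_threshold(model, decoys, fpr)
            frac = float(entry.get("threshold_fraction", 1 / 3))
            if not 0 <= frac <= 1:
                raise MotifConfigError(
                    f"motif {name}: threshold_fraction outside [0, 1]")
            trusted = min(best_window_score(model, s) for s in ungapped)
            if trusted > noise:
                model.bit_threshold = noise + frac * (trusted - noise)
            model.calibration.update(
                noise_bits=round(noise, 3), trusted_bits=round(trusted, 3),
                threshold_fraction=frac)
        library[name] = model
    for name in MANDATORY_MOTIFS:
        if name not in library:
            raise MotifConfigError(f"mandatory motif {name} not configured")
    return library
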