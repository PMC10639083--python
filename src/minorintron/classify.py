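"""Minor-intron scoring from 5' splice-site and branch-point motifs.

A transparent two-feature scorer: the first 8 intronic nt are scored with a
minor-vs-major log-odds PWM (the donor), and a 9-nt branch-point PWM is scored
against background at its best placement inside the 3' search window (40 to 5 nt
upstream of the acceptor).  The combined log-odds is calibrated to a percentile
score in [0, 100] against a pooled reference set; an intron is called minor when
its percentile score exceeds the threshold (default 90).

Non-canonically bounded introns may have their boundaries corrected: if a strong
minor donor motif lies within a short distance of the annotated 5' end, the intron
is slid to it (length preserved) and flagged as corrected.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ParameterError, TrainingError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DONOR_LEN = 8
BPS_LEN = 9
BPS_WINDOW = (-40, -5)          # search window relative to the 3' end
MIN_SCORABLE_LEN = 30

CANONICAL_5 = {"GT", "GC", "AT"}
CANONICAL_3 = {"AG", "AC"}

MODEL_FORMAT_VERSION = 1


def _count_matrix(seqs: list[str], start: int, length: int, from_end: bool = False) -> np.ndarray:
    counts = np.zeros((length, 4))
    for s in seqs:
        window = s[len(s) + start : len(s) + start + length] if from_end else s[start : start + length]
        for i, b in enumerate(window):
            if b in _BASE_INDEX:
                counts[i, _BASE_INDEX[b]] += 1
    return counts


def _pwm_from_counts(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    if pseudocount == 0 and (counts == 0).any():
        raise TrainingError("pseudocount 0 with an unseen base leaves a zero PWM cell")
    mat = counts + pseudocount
    return mat / mat.sum(axis=1, keepdims=True)


def _logodds(seq: str, num: np.ndarray, den: np.ndarray) -> float:
    """Sum of log2(num/den) over positions; unrecognised bases contribute 0."""
    score = 0.0
    for i, b in enumerate(seq):
        j = _BASE_INDEX.get(b)
        if j is not None:
            score += np.log2(num[i, j] / den[i, j])
    return score


@dataclass
class ScoringModel:
    """PWMs plus a monotone percentile calibration over a pooled reference set."""

    pwm_5ss_minor: np.ndarray
    pwm_5ss_major: np.ndarray
    pwm_bps_minor: np.ndarray
    background: np.ndarray              # length-4 base composition
    calibration: np.ndarray             # sorted combined log-odds of the reference pool
    strong_5ss_cutoff: float            # raw minor-donor log-odds for boundary correction

    def score_5ss(self, intron_seq: str) -> float:
        return _logodds(intron_seq[:DONOR_LEN], self.pwm_5ss_minor, self.pwm_5ss_major)

    def raw_5ss_minor(self, donor_seq: str) -> float:
        bg = np.tile(self.background, (DONOR_LEN, 1))
        return _logodds(donor_seq[:DONOR_LEN], self.pwm_5ss_minor, bg)

    def score_bps(self, intron_seq: str) -> float:
        """Best branch-point placement within the 3' search window."""
        n = len(intron_seq)
        lo = max(DONOR_LEN, n + BPS_WINDOW[0])
        hi = max(lo, n + BPS_WINDOW[1] - BPS_LEN + 1)
        bg = np.tile(self.background, (BPS_LEN, 1))
        best = -np.inf
        for start in range(lo, hi + 1):
            if start + BPS_LEN > n:
                break
            best = max(best, _logodds(intron_seq[start : start + BPS_LEN],
                                      self.pwm_bps_minor, bg))
        return best if np.isfinite(best) else 0.0

    def combined(self, intron_seq: str) -> float:
        return self.score_5ss(intron_seq) + self.score_bps(intron_seq)

    def minor_score(self, intron_seq: str) -> float:
        """Percentile (0..100) of the combined log-odds in the reference pool."""
        x = self.combined(intron_seq)
        return 100.0 * np.searchsorted(self.calibration, x, side="right") / self.calibration.size

    # -- serialization -----------------------------------------------------
    def to_json(self, path) -> None:
        doc = {
            "format_version": MODEL_FORMAT_VERSION,
            "pwm_5ss_minor": self.pwm_5ss_minor.tolist(),
            "pwm_5ss_major": self.pwm_5ss_major.tolist(),
            "pwm_bps_minor": self.pwm_bps_minor.tolist(),
            "background": self.background.tolist(),
            "calibration": self.calibration.tolist(),
            "strong_5ss_cutoff": self.strong_5ss_cutoff,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "ScoringModel":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise ParameterError("unsupported scoring-model format version")
        return cls(
            pwm_5ss_minor=np.array(doc["pwm_5ss_minor"]),
            pwm_5ss_major=np.array(doc["pwm_5ss_major"]),
            pwm_bps_minor=np.array(doc["pwm_bps_minor"]),
            background=np.array(doc["background"]),
            calibration=np.array(doc["calibration"]),
            strong_5ss_cutoff=doc["strong_5ss_cutoff"],
        )


def train_scorer(
    minor_reference: list[str],
    major_reference: list[str],
    pseudocount: float = 0.5,
) -> ScoringModel:
    """Estimate PWMs and fit the percentile calibration.

    References are intron sequences (>= 12 nt of 5' end, >= 40 nt of 3' end,
    >= 20 sequences per class).  The calibration is the empirical CDF of combined
    log-odds over the pooled references, so scoring the pool at threshold t calls
    ~(100 - t)% of it minor.
    """
    for name, seqs in (("minor", minor_reference), ("major", major_reference)):
        if len(seqs) < 20:
            raise TrainingError(f"need >= 20 {name} reference introns, got {len(seqs)}")
        if any(len(s) < 40 for s in seqs):
            raise TrainingError(f"{name} reference sequences must span >= 12 nt of 5' "
                                "end and >= 40 nt of 3' end")
    if sorted(minor_reference) == sorted(major_reference):
        warnings.warn("identical minor and major references: calibration is degenerate",
                      stacklevel=2)

    pwm5_minor = _pwm_from_counts(_count_matrix(minor_reference, 0, DONOR_LEN), pseudocount)
    pwm5_major = _pwm_from_counts(_count_matrix(major_reference, 0, DONOR_LEN), pseudocount)

    # branch point: align reference minor introns on their best window against an
    # initial PWM built from the fixed canonical offset, then re-estimate once
    init = _pwm_from_counts(
        _count_matrix(minor_reference, -12 - BPS_LEN, BPS_LEN, from_end=True),
        max(pseudocount, 0.5),
    )
    bg_counts = np.zeros(4)
    for s in minor_reference + major_reference:
        for b in s:
            if b in _BASE_INDEX:
                bg_counts[_BASE_INDEX[b]] += 1
    background = (bg_counts + 1.0) / (bg_counts + 1.0).sum()

    tmp = ScoringModel(pwm5_minor, pwm5_major, init, background,
                       calibration=np.zeros(1), strong_5ss_cutoff=np.inf)
    best_windows = []
    bgm = np.tile(background, (BPS_LEN, 1))
    for s in minor_reference:
        n = len(s)
        lo = max(DONOR_LEN, n + BPS_WINDOW[0])
        hi = max(lo, n + BPS_WINDOW[1] - BPS_LEN + 1)
        scores = [(_logodds(s[i : i + BPS_LEN], init, bgm), i)
                  for i in range(lo, min(hi + 1, n - BPS_LEN + 1))]
        if scores:
            best_windows.append(s[max(scores)[1] : max(scores)[1] + BPS_LEN])
    pwm_bps = _pwm_from_counts(_count_matrix(best_windows, 0, BPS_LEN), pseudocount)

    model = ScoringModel(pwm5_minor, pwm5_major, pwm_bps, background,
                         calibration=np.zeros(1), strong_5ss_cutoff=np.inf)
    pool = sorted(model.combined(s) for s in minor_reference + major_reference)
    raw5 = [model.raw_5ss_minor(s) for s in minor_reference]
    return ScoringModel(
        pwm5_minor, pwm5_major, pwm_bps, background,
        calibration=np.array(pool),
        strong_5ss_cutoff=float(np.percentile(raw5, 95)),
    )


def load_packaged_references() -> tuple[list[str], list[str]]:
    """Synthetic reference intron sets shipped with the package (minor, major).

    These are stand-ins generated from the package's own motif model, not curated
    biological introns; filenames carry the ``synthetic`` label.
    """
    out = []
    for name in ("minor_ref_synthetic.fa", "major_ref_synthetic.fa"):
        text = resources.files("minorintron.data").joinpath(name).read_text()
        seqs, cur = [], []
        for line in text.splitlines():
            if line.startswith(">"):
                if cur:
                    seqs.append("".join(cur))
                cur = []
            else:
                cur.append(line.strip())
        if cur:
            seqs.append("".join(cur))
        out.append(seqs)
    return out[0], out[1]


def load_default_model() -> ScoringModel:
    minor, major = load_packaged_references()
    return train_scorer(minor, major)


# ---------------------------------------------------------------------------
# boundary correction and classification
# ---------------------------------------------------------------------------

def is_canonical(terminus_5: str, terminus_3: str) -> bool:
    return terminus_5 in CANONICAL_5 and terminus_3 in CANONICAL_3


@dataclass
class CorrectionResult:
    sequence: str
    shift: int
    corrected: bool


def correct_boundaries(
    sequence: str,
    model: ScoringModel,
    max_shift: int = 10,
    upstream_flank: str = "",
    downstream_flank: str = "",
) -> CorrectionResult:
    """Slide a non-canonically bounded intron onto a nearby strong minor donor.

    Canonical introns are never touched.  Candidate shifts move both boundaries by
    the same offset (length preserved); a shift is accepted only if the candidate
    donor's raw minor log-odds reaches the model's strong-donor cutoff.  The
    best-scoring candidate wins; ties go to the smallest |shift|.
    """
    t5, t3 = sequence[:2], sequence[-2:]
    if is_canonical(t5, t3):
        return CorrectionResult(sequence, 0, False)
    best: tuple[float, int, str] | None = None
    for delta in range(-max_shift, max_shift + 1):
        if delta == 0:
            continue
        if delta > 0:
            if len(downstream_flank) < delta:
                continue
            cand = sequence[delta:] + downstream_flank[:delta]
        else:
            if len(upstream_flank) < -delta:
                continue
            cand = upstream_flank[delta:] + sequence[:delta]
        score = model.raw_5ss_minor(cand[:DONOR_LEN])
        if score >= model.strong_5ss_cutoff:
            key = (score, -abs(delta), cand)
            if best is None or key > (best[0], -abs(best[1]), best[2]):
                best = (score, delta, cand)
    if best is None:
        return CorrectionResult(sequence, 0, False)
    return CorrectionResult(best[2], best[1], True)


def subtype_from_termini(t5: str, t3: str) -> str:
    pair = f"{t5}-{t3}"
    return pair if pair in {"GT-AG", "GC-AG", "AT-AC"} else "other"


def score_and_classify(
    model: ScoringModel,
    introns,
    threshold: float = 90.0,
    correct: bool = True,
    max_shift: int = 10,
    genome: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Score IntronRecords and call types: minor iff minor_score > threshold.

    ``introns`` is an iterable of IntronRecord (sequence required).  When a genome
    dict is supplied, flanking sequence is available for boundary correction of
    non-canonical introns.  Introns too short to score are flagged and skipped.
    """
    if not 0 < threshold <= 100:
        raise ParameterError("threshold must be in (0, 100]")
    from .synthetic import revcomp as _rc

    rows = []
    for r in introns:
        seq = r.sequence
        if len(seq) < MIN_SCORABLE_LEN:
            rows.append({"intron_id": r.intron_id, "gene_id": r.gene_id,
                         "score_5ss": np.nan, "score_bps": np.nan,
                         "minor_score": np.nan, "type_call": "unscored",
                         "boundary_corrected": False, "shift": 0,
                         "subtype": subtype_from_termini(r.terminus_5, r.terminus_3),
                         "flag": "too_short"})
            continue
        corrected, shift = False, 0
        if correct and not is_canonical(seq[:2], seq[-2:]):
            up = down = ""
            if genome is not None and r.contig in genome:
                contig = genome[r.contig]
                lo, hi = r.start - 1, r.end
                if r.strand == "+":
                    up = contig[max(0, lo - max_shift) : lo]
                    down = contig[hi : hi + max_shift]
                else:
                    up = _rc(contig[hi : hi + max_shift])
                    down = _rc(contig[max(0, lo - max_shift) : lo])
            res = correct_boundaries(seq, model, max_shift, up, down)
            seq, shift, corrected = res.sequence, res.shift, res.corrected
        s5 = model.score_5ss(seq)
        sb = model.score_bps(seq)
        score = model.minor_score(seq)
        rows.append({
            "intron_id": r.intron_id,
            "gene_id": r.gene_id,
            "score_5ss": s5,
            "score_bps": sb,
            "minor_score": score,
            "type_call": "minor" if score > threshold else "major",
            "boundary_corrected": corrected,
            "shift": shift,
            "subtype": subtype_from_termini(seq[:2], seq[-2:]),
            "flag": "",
        })
    return pd.DataFrame(rows)


def classification_summary(calls: pd.DataFrame) -> dict:
    """Per-genome minor counts and minor intron density (% of scored introns)."""
    scored = calls[calls["type_call"] != "unscored"]
    n_minor = int((scored["type_call"] == "minor").sum())
    minor = scored[scored["type_call"] == "minor"]
    n_corrected = int(minor["boundary_corrected"].sum())
    return {
        "n_introns": int(len(scored)),
        "n_minor": n_minor,
        "minor_density_pct": 100.0 * n_minor / len(scored) if len(scored) else 0.0,
        "corrected_fraction": n_corrected / n_minor if n_minor else 0.0,
        "n_uncorrected_atac": int(((minor["subtype"] == "AT-AC")
                                   & ~minor["boundary_corrected"]).sum()),
    }
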