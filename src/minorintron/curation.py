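"""Species-level curation: confident minor-intron presence, absence or uncertainty.

Evidence per species: the number of called minor introns, the fraction of those with
corrected (originally non-canonical) boundaries, how many of the four minor snRNAs
(U11, U12, U4atac, U6atac) were detected, uncorrected AT-AC minor calls, annotation
provenance and BUSCO completeness.  The decision rules:

* PRESENT: corrected fraction <= 0.25, >= 3 minor introns, >= 2 minor snRNAs.
* ABSENT: (<= 3 minor introns and < 2 snRNAs) OR (<= 5 minor introns, < 2 snRNAs,
  < 5 uncorrected AT-AC calls, and either RefSeq annotation or a BUSCO score not far
  below the species' clade: >= B_Q1 - 1.5 * B_IQR).
* A would-be ABSENT species with minor intron density >= 1% is instead UNCERTAIN
  (massive total intron loss can make a handful of false positives look like an
  outstandingly high minor intron density).
* Everything else: UNCERTAIN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ParameterError

MINOR_SNRNAS = ("U11", "U12", "U4atac", "U6atac")


@dataclass(frozen=True)
class SpeciesEvidence:
    n_minor: int
    corrected_fraction: float
    n_snrna: int
    n_uncorrected_atac: int = 0
    busco: float | None = None
    annotation_source: str = "other"     # 'RefSeq' or 'other'
    minor_density: float = 0.0           # percent of all introns

    def __post_init__(self) -> None:
        if not 0.0 <= self.corrected_fraction <= 1.0:
            raise ParameterError("corrected_fraction must be in [0, 1]")
        if self.n_snrna not in range(5):
            raise ParameterError("n_snrna must be in 0..4")
        if self.n_minor < 0 or self.n_uncorrected_atac < 0:
            raise ParameterError("counts must be non-negative")


@dataclass(frozen=True)
class CladeBuscoStats:
    clade: str
    b_q1: float
    b_iqr: float

    @property
    def threshold(self) -> float:
        return self.b_q1 - 1.5 * self.b_iqr


@dataclass(frozen=True)
class CurationVerdict:
    verdict: str                 # 'present' | 'absent' | 'uncertain'
    triggered_rules: tuple[str, ...]


def count_minor_snrnas(hits: pd.DataFrame, evalue_max: float = 0.01) -> int:
    """Distinct minor snRNAs with at least one hit at E <= cutoff.

    ``hits`` needs columns 'snrna' and 'evalue' (the consumed covariance-model
    search table).
    """
    if hits.empty:
        return 0
    ok = hits[hits["evalue"] <= evalue_max]
    return int(ok["snrna"].isin(MINOR_SNRNAS).groupby(ok["snrna"]).any().sum())


def clade_busco_stats(scores_by_clade: dict[str, list[float]]) -> dict[str, CladeBuscoStats]:
    """First quartile and inner quartile range of BUSCO scores per clade.

    Quantiles use linear interpolation (type 7); >= 4 species per clade required.
    """
    out = {}
    for clade, scores in scores_by_clade.items():
        if len(scores) < 4:
            raise InsufficientDataError(
                f"clade {clade!r} has {len(scores)} species; >= 4 needed for quartiles")
        q1, q3 = np.percentile(np.asarray(scores, dtype=float), [25, 75])
        out[clade] = CladeBuscoStats(clade, float(q1), float(q3 - q1))
    return out


def curate_species(
    ev: SpeciesEvidence,
    clade_stats: CladeBuscoStats | None = None,
) -> CurationVerdict:
    """Apply the presence/absence decision rules to one species."""
    rules: list[str] = []

    if ev.corrected_fraction <= 0.25 and ev.n_minor >= 3 and ev.n_snrna >= 2:
        return CurationVerdict("present", ("presence_criteria",))

    absent = False
    if ev.n_minor <= 3 and ev.n_snrna < 2:
        absent = True
        rules.append("absence_few_minor_few_snrna")
    if not absent and ev.n_minor <= 5 and ev.n_snrna < 2 and ev.n_uncorrected_atac < 5:
        if ev.annotation_source == "RefSeq":
            absent = True
            rules.append("absence_refseq")
        elif ev.busco is not None and clade_stats is not None:
            if ev.busco >= clade_stats.threshold:
                absent = True
                rules.append("absence_busco_ok")
        else:
            return CurationVerdict("uncertain", ("insufficient_evidence",))

    if absent:
        if ev.minor_density >= 1.0:
            return CurationVerdict("uncertain",
                                   tuple(rules) + ("high_density_override",))
        return CurationVerdict("absent", tuple(rules))
    return CurationVerdict("uncertain", ("no_rule_matched",))


def curate_table(
    evidence: pd.DataFrame,
    clade_stats: dict[str, CladeBuscoStats] | None = None,
) -> pd.DataFrame:
    """Vector form: one species per row; columns mirror SpeciesEvidence fields
    plus 'species' and optional 'clade'."""
    rows = []
    for _, r in evidence.iterrows():
        ev = SpeciesEvidence(
            n_minor=int(r["n_minor"]),
            corrected_fraction=float(r["corrected_fraction"]),
            n_snrna=int(r["n_snrna"]),
            n_uncorrected_atac=int(r.get("n_uncorrected_atac", 0)),
            busco=float(r["busco"]) if "busco" in r and pd.notna(r["busco"]) else None,
            annotation_source=str(r.get("annotation_source", "other")),
            minor_density=float(r.get("minor_density", 0.0)),
        )
        stats = None
        if clade_stats and "clade" in r and pd.notna(r["clade"]):
            stats = clade_stats.get(str(r["clade"]))
        v = curate_species(ev, stats)
        rows.append({"species": r["species"], "verdict": v.verdict,
                     "triggered_rules": ";".join(v.triggered_rules)})
    return pd.DataFrame(rows, columns=["species", "verdict", "triggered_rules"])
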