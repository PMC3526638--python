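"""Target-decoy filtering of peptide-spectrum matches and protein inference.

A PSM table (peptide, protein accessions, charge, Xcorr, deltaCn, decoy
flag) is filtered with a fixed deltaCn floor and per-charge Xcorr
thresholds chosen against a PSM-level FDR target.  The decoy hits — matches
against reversed protein sequences — estimate the number of false matches
among accepted targets, assuming incorrect target matches and decoy matches
are equally likely.  Passing PSMs are collapsed to protein groups by greedy
parsimony, and protein-level FDR is the naive decoy-group / target-group
ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PSMRecord",
    "ProteinGroup",
    "FDRResult",
    "ThresholdNotAttainableError",
    "DELTA_CN_MIN",
    "estimate_psm_fdr",
    "select_thresholds",
    "group_proteins",
    "estimate_protein_fdr",
    "filter_psms",
    "read_psm_tsv",
    "write_psm_tsv",
    "write_protein_groups_tsv",
]

#: deltaCn floor applied regardless of charge state.
DELTA_CN_MIN = 0.1

DEFAULT_DECOY_PREFIX = "REV_"


class ThresholdNotAttainableError(ValueError):
    """No Xcorr threshold reaches the requested FDR (distinct from empty input)."""


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match with its search-engine scores."""

    spectrum_id: str
    peptide: str
    accessions: tuple[str, ...]
    charge: int
    xcorr: float
    delta_cn: float
    is_decoy: bool

    def __post_init__(self) -> None:
        if not self.accessions:
            raise ValueError("a PSM must carry at least one accession")
        if self.xcorr < 0:
            raise ValueError("Xcorr must be non-negative")
        if not 0.0 <= self.delta_cn <= 1.0:
            raise ValueError("deltaCn must lie in [0, 1]")


@dataclass
class ProteinGroup:
    """Accessions indistinguishable given the observed peptides, plus counts."""

    group_id: str
    accessions: tuple[str, ...]
    peptides: frozenset[str]
    psm_count: int
    is_decoy: bool


@dataclass
class FDRResult:
    threshold_per_charge: dict[int, float]
    psm_fdr: float
    protein_fdr: float
    n_target_proteins: int
    n_decoy_proteins: int


# ---------------------------------------------------------------------------
# array helpers


def _columns(psms: list[PSMRecord]):
    charge = np.array([p.charge for p in psms])
    xcorr = np.array([p.xcorr for p in psms])
    dcn = np.array([p.delta_cn for p in psms])
    decoy = np.array([p.is_decoy for p in psms])
    return charge, xcorr, dcn, decoy


def _pass_mask(charge, xcorr, dcn, thresholds: dict[int, float]) -> np.ndarray:
    mask = dcn >= DELTA_CN_MIN
    thr = np.empty_like(xcorr)
    for c in np.unique(charge):
        if int(c) not in thresholds:
            raise KeyError(f"no Xcorr threshold provided for charge {int(c)}+")
        thr[charge == c] = thresholds[int(c)]
    return mask & (xcorr >= thr)


# ---------------------------------------------------------------------------
# operations


def estimate_psm_fdr(psms: list[PSMRecord], thresholds: dict[int, float]) -> float:
    """Decoy/target ratio among PSMs passing the joint filter.

    The filter keeps PSMs with ``deltaCn >= 0.1`` and
    ``Xcorr >= thresholds[charge]``.  Returns 0 when no target passes.
    """
    if not psms:
        raise ValueError("empty PSM list")
    charge, xcorr, dcn, decoy = _columns(psms)
    passing = _pass_mask(charge, xcorr, dcn, thresholds)
    n_target = int((passing & ~decoy).sum())
    n_decoy = int((passing & decoy).sum())
    return n_decoy / n_target if n_target else 0.0


def select_thresholds(psms: list[PSMRecord], fdr_target: float) -> dict[int, float]:
    """Smallest per-charge Xcorr thresholds meeting the PSM FDR target.

    For every observed charge state, candidate thresholds are the observed
    Xcorr values of that charge; the smallest one whose within-charge
    target-decoy FDR (after the deltaCn floor) is below ``fdr_target`` —
    with at least one target still passing — is selected.  Because the
    pooled FDR is a count-weighted mediant of the per-charge ratios, each
    charge meeting the target implies the joint filter does too.
    Monotone: a looser target never raises a threshold.
    """
    if not 0 < fdr_target < 1:
        raise ValueError("fdr_target must lie strictly between 0 and 1")
    if not psms:
        raise ValueError("empty PSM list")
    charge, xcorr, dcn, decoy = _columns(psms)
    ok = dcn >= DELTA_CN_MIN
    thresholds: dict[int, float] = {}
    for c in np.unique(charge):
        sel = ok & (charge == c)
        scores = xcorr[sel]
        dec = decoy[sel]
        if scores.size == 0:
            # nothing of this charge survives the deltaCn floor; any cut works
            thresholds[int(c)] = float(xcorr[charge == c].min())
            continue
        found = None
        for t in np.unique(scores):  # ascending
            passing = scores >= t
            n_t = int((passing & ~dec).sum())
            if n_t == 0:
                continue  # an empty identification cannot "achieve" the target
            if (passing & dec).sum() / n_t < fdr_target:
                found = float(t)
                break
        if found is None:
            raise ThresholdNotAttainableError(
                f"charge {int(c)}+: no Xcorr threshold achieves FDR < {fdr_target}"
            )
        thresholds[int(c)] = found
    return thresholds


def filter_psms(psms: list[PSMRecord], thresholds: dict[int, float]) -> list[PSMRecord]:
    """PSMs surviving the deltaCn floor and per-charge Xcorr thresholds."""
    charge, xcorr, dcn, _ = _columns(psms)
    passing = _pass_mask(charge, xcorr, dcn, thresholds)
    return [p for p, keep in zip(psms, passing) if keep]


def group_proteins(
    psms: list[PSMRecord],
    decoy_prefix: str = DEFAULT_DECOY_PREFIX,
) -> list[ProteinGroup]:
    """Greedy parsimony protein grouping of threshold-filtered PSMs.

    Peptides are iteratively assigned to the accession covering the most
    still-unassigned peptides (ties: lexicographically first accession).
    Accessions with identical observed peptide sets merge into one group;
    accessions whose peptides are a strict subset of an earlier group's are
    absorbed and emit no group of their own.  Every passing PSM is counted
    in exactly one group (the group that claimed its peptide), so PSM
    counts are conserved.  A group is decoy iff all its accessions carry
    the decoy marker.
    """
    if not psms:
        return []
    pep_by_acc: dict[str, set[str]] = {}
    psms_by_pep: dict[str, int] = {}
    for p in psms:
        psms_by_pep[p.peptide] = psms_by_pep.get(p.peptide, 0) + 1
        for acc in p.accessions:
            pep_by_acc.setdefault(acc, set()).add(p.peptide)

    remaining = set(psms_by_pep)
    groups: list[ProteinGroup] = []
    while remaining:
        best_acc, best_cov = None, 0
        for acc in sorted(pep_by_acc):
            cov = len(pep_by_acc[acc] & remaining)
            if cov > best_cov:
                best_acc, best_cov = acc, cov
        if best_acc is None:  # pragma: no cover - cannot happen while remaining
            break
        members = tuple(
            sorted(a for a in pep_by_acc if pep_by_acc[a] == pep_by_acc[best_acc])
        )
        claimed = pep_by_acc[best_acc] & remaining
        remaining -= claimed
        groups.append(
            ProteinGroup(
                group_id=members[0],
                accessions=members,
                peptides=frozenset(claimed),
                psm_count=sum(psms_by_pep[p] for p in claimed),
                is_decoy=all(a.startswith(decoy_prefix) for a in members),
            )
        )
    return groups


def estimate_protein_fdr(
    groups: list[ProteinGroup],
    thresholds: dict[int, float] | None = None,
    psm_fdr: float = float("nan"),
) -> FDRResult:
    """Naive target-decoy protein FDR: decoy groups / target groups.

    The expected number of false positive target identifications is
    approximated by the number of decoy identifications.  Defined as 0
    (with a warning) when no target group exists.
    """
    n_decoy = sum(g.is_decoy for g in groups)
    n_target = len(groups) - n_decoy
    if n_target == 0:
        warnings.warn("no target protein groups; protein FDR defined as 0")
        fdr = 0.0
    else:
        fdr = n_decoy / n_target
    return FDRResult(
        threshold_per_charge=dict(thresholds or {}),
        psm_fdr=psm_fdr,
        protein_fdr=fdr,
        n_target_proteins=n_target,
        n_decoy_proteins=n_decoy,
    )


def filter_and_group(
    psms: list[PSMRecord],
    fdr_target: float = 0.01,
    decoy_prefix: str = DEFAULT_DECOY_PREFIX,
) -> tuple[list[PSMRecord], list[ProteinGroup], FDRResult]:
    """Threshold selection, filtering, grouping and FDR summary in one call."""
    thresholds = select_thresholds(psms, fdr_target)
    psm_fdr = estimate_psm_fdr(psms, thresholds)
    passing = filter_psms(psms, thresholds)
    groups = group_proteins(passing, decoy_prefix=decoy_prefix)
    result = estimate_protein_fdr(groups, thresholds, psm_fdr)
    return passing, groups, result


# ---------------------------------------------------------------------------
# TSV interfaces


def write_psm_tsv(psms: list[PSMRecord], path) -> None:
    frame = pd.DataFrame(
        {
            "spectrum_id": [p.spectrum_id for p in psms],
            "peptide": [p.peptide for p in psms],
            "accessions": [";".join(p.accessions) for p in psms],
            "charge": [p.charge for p in psms],
            "xcorr": [p.xcorr for p in psms],
            "delta_cn": [p.delta_cn for p in psms],
            "is_decoy": [int(p.is_decoy) for p in psms],
        }
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_psm_tsv(path) -> list[PSMRecord]:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        PSMRecord(
            spectrum_id=str(r.spectrum_id),
            peptide=str(r.peptide),
            accessions=tuple(str(r.accessions).split(";")),
            charge=int(r.charge),
            xcorr=float(r.xcorr),
            delta_cn=float(r.delta_cn),
            is_decoy=bool(r.is_decoy),
        )
        for r in frame.itertuples(index=False)
    ]


def write_protein_groups_tsv(groups: list[ProteinGroup], path) -> None:
    frame = pd.DataFrame(
        {
            "group_id": [g.group_id for g in groups],
            "accessions": [";".join(g.accessions) for g in groups],
            "n_peptides": [len(g.peptides) for g in groups],
            "psm_count": [g.psm_count for g in groups],
            "is_decoy": [int(g.is_decoy) for g in groups],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
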