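"""Concordance between a predicted structure and enzymatic probing cuts.

RNase T1 cleaves after single-stranded G residues; RNase V1 cleaves within
double-stranded RNA. Cut tables are categorical (gel intensities digitized
as none/weak/strong), keyed by probe position, enzyme and condition
(folding-promoting vs denaturing).

Verdicts per observed cut:

* V1 under folding conditions — concordant iff the position is paired.
* T1 under folding conditions — concordant iff the base is an unpaired G;
  a T1 cut at a *paired* G is classed ``metastable_consistent``: it signals
  a structure sampling unfolded states (dynamic unfolding/folding cycles),
  not a wrong prediction, and is excluded from the concordant/discordant
  tally.
* T1 under denaturing conditions — base identity only (concordant iff G).
* V1 under denaturing conditions — uninformative (excluded).

Summaries are concordant / (concordant + discordant) per enzyme-condition;
an empty denominator is reported as undefined (None), not as 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .seqio import RnaSequence, SecondaryStructure, SeqFormatError

__all__ = [
    "ProbingRecord",
    "ProbingDataset",
    "read_probing_tsv",
    "write_probing_tsv",
    "concordance",
    "ConcordanceReport",
]

ENZYMES = ("T1", "V1")
CONDITIONS = ("fold", "denature")
INTENSITIES = ("none", "weak", "strong")


@dataclass(frozen=True)
class ProbingRecord:
    position: int  # 1-based nt in the probe
    enzyme: str
    condition: str
    intensity: str

    def __post_init__(self) -> None:
        if self.enzyme not in ENZYMES:
            raise SeqFormatError(f"unknown enzyme {self.enzyme!r} (expected T1/V1)")
        if self.condition not in CONDITIONS:
            raise SeqFormatError(
                f"unknown condition {self.condition!r} (expected fold/denature)"
            )
        if self.intensity not in INTENSITIES:
            raise SeqFormatError(
                f"unknown intensity {self.intensity!r} (expected none/weak/strong)"
            )
        if self.position < 1:
            raise SeqFormatError(f"position {self.position} must be >= 1")


@dataclass(frozen=True)
class ProbingDataset:
    records: tuple[ProbingRecord, ...]

    def __post_init__(self) -> None:
        keys = [(r.position, r.enzyme, r.condition) for r in self.records]
        dupes = {k for k in keys if keys.count(k) > 1}
        if dupes:
            raise SeqFormatError(
                f"duplicate (position, enzyme, condition) record(s): {sorted(dupes)}"
            )

    def cuts(self) -> list[ProbingRecord]:
        """Records with an observed cut (intensity != none)."""
        return [r for r in self.records if r.intensity != "none"]

    def __len__(self) -> int:
        return len(self.records)


def read_probing_tsv(path: str | Path) -> ProbingDataset:
    """Read a 4-column TSV (position, enzyme, condition, intensity) with header."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["position", "enzyme", "condition", "intensity"]
    if list(df.columns) != expected:
        raise SeqFormatError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )
    records = tuple(
        ProbingRecord(int(row.position), row.enzyme, row.condition, row.intensity)
        for row in df.itertuples()
    )
    return ProbingDataset(records)


def write_probing_tsv(path: str | Path, dataset: ProbingDataset) -> None:
    df = pd.DataFrame(
        [
            {
                "position": r.position,
                "enzyme": r.enzyme,
                "condition": r.condition,
                "intensity": r.intensity,
            }
            for r in dataset.records
        ],
        columns=["position", "enzyme", "condition", "intensity"],
    )
    df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ConcordanceReport:
    verdicts: tuple[dict, ...]
    summaries: dict  # (enzyme, condition) -> fraction or None


def concordance(
    structure: SecondaryStructure,
    seq: RnaSequence,
    dataset: ProbingDataset,
    probe_offset: int = 0,
) -> ConcordanceReport:
    """Score agreement of probing cuts with a predicted structure.

    ``probe_offset`` maps probe positions to structure coordinates
    (structure position = probe position + offset). ``seq`` supplies base
    identities on the structure's coordinate system.
    """
    if structure.length > len(seq):
        raise SeqFormatError("structure longer than sequence")
    paired = set(structure.pair_table)
    verdicts = []
    tallies: dict[tuple[str, str], dict[str, int]] = {}
    for rec in sorted(
        dataset.cuts(), key=lambda r: (r.enzyme, r.condition, r.position)
    ):
        pos = rec.position + probe_offset
        if not 1 <= pos <= structure.length:
            raise SeqFormatError(
                f"cut at probe position {rec.position} maps to {pos}, outside "
                f"the structure (length {structure.length})"
            )
        base = seq.base(pos)
        is_paired = pos in paired
        if rec.enzyme == "V1":
            verdict = (
                ("concordant" if is_paired else "discordant")
                if rec.condition == "fold"
                else "uninformative"
            )
        else:  # T1
            if rec.condition == "denature":
                verdict = "concordant" if base == "G" else "discordant"
            elif base != "G":
                verdict = "discordant"
            elif is_paired:
                verdict = "metastable_consistent"
            else:
                verdict = "concordant"
        verdicts.append(
            {
                "position": rec.position,
                "structure_position": pos,
                "enzyme": rec.enzyme,
                "condition": rec.condition,
                "intensity": rec.intensity,
                "base": base,
                "paired": is_paired,
                "verdict": verdict,
            }
        )
        t = tallies.setdefault((rec.enzyme, rec.condition), {"c": 0, "d": 0})
        if verdict == "concordant":
            t["c"] += 1
        elif verdict == "discordant":
            t["d"] += 1
    summaries = {}
    for key, t in tallies.items():
        denom = t["c"] + t["d"]
        summaries[key] = t["c"] / denom if denom else None
    return ConcordanceReport(tuple(verdicts), summaries)
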