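"""The proposed diagnostic decision workflow as an executable classifier.

For a sample with clinically/radiologically suspected Ewing sarcoma:
stain CD99 first; if CD99 IRS is at or below the screening cut-off
(default 2) Ewing sarcoma is unlikely.  If CD99 is positive and
molecular diagnostics (FISH, qRT-PCR, NGS) are available, they are the
preferred confirmation.  Otherwise BCL11B and GLG1 are stained and
scored: high expression of one or both (IRS above the high cut-off,
default 9) means the diagnosis should be strongly considered; if
neither is high the diagnosis is not confirmed by IHC - which does not
exclude Ewing sarcoma, since roughly a fifth of true cases lack high
BCL11B/GLG1 staining.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .containers import TMADataset, ValidationError


class Verdict(str, Enum):
    EWING_UNLIKELY = "EWING_UNLIKELY"
    MOLECULAR_CONFIRMATION = "MOLECULAR_CONFIRMATION"
    EWING_STRONGLY_CONSIDERED = "EWING_STRONGLY_CONSIDERED"
    EWING_NOT_CONFIRMED = "EWING_NOT_CONFIRMED"


@dataclass(frozen=True)
class WorkflowInput:
    """Marker scores of one sample entering the workflow.

    BCL11B/GLG1 IRS may be None (not yet stained) as long as the CD99
    gate fails or molecular confirmation is available.
    """

    cd99_irs: int
    bcl11b_irs: int | None = None
    glg1_irs: int | None = None
    molecular_available: bool = False

    def __post_init__(self) -> None:
        for name, v in (("cd99", self.cd99_irs), ("bcl11b", self.bcl11b_irs),
                        ("glg1", self.glg1_irs)):
            if v is not None and not 0 <= v <= 12:
                raise ValidationError(f"{name} IRS must be in [0, 12], got {v}")


@dataclass(frozen=True)
class Gates:
    """Workflow cut-offs: CD99 screening gate and the BCL11B/GLG1
    high-expression gate (both strict '>')."""

    cd99_cutoff: int = 2
    high_cutoff: int = 9


@dataclass(frozen=True)
class Recommendation:
    verdict: Verdict
    rationale: tuple[str, ...]

    def as_dict(self) -> dict:
        return {"verdict": self.verdict.value, "rationale": list(self.rationale)}


def classify_sample(inp: WorkflowInput, gates: Gates = Gates()) -> Recommendation:
    """Run one sample through the decision workflow (pure function)."""
    trail = []
    if inp.cd99_irs <= gates.cd99_cutoff:
        trail.append(f"CD99 IRS {inp.cd99_irs} <= {gates.cd99_cutoff}: "
                     "screening stain negative")
        return Recommendation(Verdict.EWING_UNLIKELY, tuple(trail))
    trail.append(f"CD99 IRS {inp.cd99_irs} > {gates.cd99_cutoff}: "
                 "screening stain positive")
    if inp.molecular_available:
        trail.append("molecular diagnostics available: confirm by "
                     "FISH/qRT-PCR/NGS (preferred)")
        return Recommendation(Verdict.MOLECULAR_CONFIRMATION, tuple(trail))
    trail.append("molecular diagnostics unavailable: stain BCL11B and GLG1")
    if inp.bcl11b_irs is None or inp.glg1_irs is None:
        raise ValidationError(
            "BCL11B and GLG1 IRS required: stain and score both markers"
        )
    high = []
    for name, v in (("BCL11B", inp.bcl11b_irs), ("GLG1", inp.glg1_irs)):
        if v > gates.high_cutoff:
            high.append(name)
            trail.append(f"{name} IRS {v} > {gates.high_cutoff}: highly expressed")
        else:
            trail.append(f"{name} IRS {v} <= {gates.high_cutoff}: not highly expressed")
    if high:
        trail.append("one or both auxiliary markers highly expressed: "
                     "Ewing sarcoma strongly considered")
        return Recommendation(Verdict.EWING_STRONGLY_CONSIDERED, tuple(trail))
    trail.append("neither auxiliary marker highly expressed: diagnosis not "
                 "confirmed by IHC; this does NOT exclude Ewing sarcoma "
                 "(about one in five true cases lacks high BCL11B/GLG1)")
    return Recommendation(Verdict.EWING_NOT_CONFIRMED, tuple(trail))


def classify_dataset(tma: TMADataset, gates: Gates = Gates(),
                     molecular_available: bool = False) -> dict[str, Recommendation]:
    """Batch-classify every sample of a TMA dataset."""
    for marker in ("CD99", "BCL11B", "GLG1"):
        if marker not in tma.scores.columns:
            raise ValidationError(f"dataset lacks marker {marker!r}")
    out = {}
    for sample_id, row in tma.scores.iterrows():
        inp = WorkflowInput(cd99_irs=int(row["CD99"]), bcl11b_irs=int(row["BCL11B"]),
                            glg1_irs=int(row["GLG1"]),
                            molecular_available=molecular_available)
        out[sample_id] = classify_sample(inp, gates)
    return out
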