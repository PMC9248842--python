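"""Validation reports: text summary, -log(p) bar plot, JSON round trip."""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .assignment import AssignmentResult, ReferenceMatch
from .validator import (ChainResult, IssueRegion, OutcomeClass,
                        ValidationConfig, classify_outcome)

SCHEMA_VERSION = 1


@dataclass
class ValidationReport:
    """Per-chain assignment results, merged issues and run metadata."""

    chains: list[ChainResult]
    config: ValidationConfig
    metadata: dict = field(default_factory=dict)

    @property
    def has_issues(self) -> bool:
        return any(c.issues for c in self.chains)

    # -- JSON round trip ----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "metadata": self.metadata,
            "config": asdict(self.config),
            "chains": [_chain_to_dict(c) for c in self.chains],
        }
        text = json.dumps(payload, indent=2) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ValidationReport":
        text = Path(source).read_text() if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).exists()
        ) else str(source)
        payload = json.loads(text)
        if payload.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported report schema: {payload.get('schema_version')}")
        config = ValidationConfig(**payload["config"])
        chains = [_chain_from_dict(d) for d in payload["chains"]]
        return cls(chains=chains, config=config, metadata=payload.get("metadata", {}))


def _chain_to_dict(c: ChainResult) -> dict:
    return {
        "chain_id": c.chain_id,
        "reference_match": asdict(c.reference_match) if c.reference_match else None,
        "skipped_reason": c.skipped_reason,
        "results": [asdict(r) for r in c.results],
        "issues": [asdict(i) for i in c.issues],
    }


def _chain_from_dict(d: dict) -> ChainResult:
    match = ReferenceMatch(**d["reference_match"]) if d.get("reference_match") else None
    return ChainResult(
        chain_id=d["chain_id"],
        reference_match=match,
        results=[AssignmentResult(**r) for r in d.get("results", [])],
        issues=[IssueRegion(**i) for i in d.get("issues", [])],
        skipped_reason=d.get("skipped_reason"),
    )


# -- text report ------------------------------------------------------------

_ISSUE_TITLES = {
    "no_reference": "Unidentified reference sequence",
    "register_shift": "Plausible register shift",
    "sequence_mismatch": "Sequence mismatch",
    "numbering_problem": "Residue numbering problem",
}


def render_text(report: ValidationReport) -> str:
    """Human-readable summary: per chain, the reference identification,
    outcome tallies and every issue with its residue range and, for
    register shifts, the suggested corrected sequence assignment."""
    lines: list[str] = []
    lines.append("Sequence-register validation report")
    lines.append("=" * 35)
    for chain in report.chains:
        lines.append("")
        lines.append(f"Chain {chain.chain_id}")
        lines.append("-" * (6 + len(chain.chain_id)))
        if chain.skipped_reason:
            lines.append(f"  skipped: {chain.skipped_reason}")
            continue
        if chain.reference_match is None:
            lines.append("  reference sequence cannot be identified "
                         "(missing input sequence, very low local resolution, "
                         "or a mistraced chain)")
            continue
        m = chain.reference_match
        lines.append(f"  reference: {m.sequence_id} (E-value {m.e_value:.2e})")
        counts = chain.outcome_counts(report.config.p_threshold)
        lines.append("  fragments: "
                     f"{counts[OutcomeClass.CONFIRMED.value]} confirmed, "
                     f"{counts[OutcomeClass.INCONCLUSIVE.value]} inconclusive, "
                     f"{counts[OutcomeClass.REGISTER_ERROR.value]} flagged")
        real_issues = [i for i in chain.issues if i.issue_type != "no_reference"]
        if not real_issues:
            lines.append("  no issues detected")
            continue
        for issue in real_issues:
            title = _ISSUE_TITLES.get(issue.issue_type, issue.issue_type)
            span = (f"{issue.first_residue_number}"
                    if issue.first_residue_number == issue.last_residue_number
                    else f"{issue.first_residue_number}-{issue.last_residue_number}")
            lines.append(f"  {title}: residues {span}")
            if issue.issue_type == "register_shift":
                lines.append(f"    suggested shift: {issue.suggested_shift:+d} residues"
                             f" (p = {issue.best_p_value:.2e})")
                if issue.suggested_sequence:
                    lines.append(f"    suggested assignment: {issue.suggested_sequence}")
            elif issue.detail:
                lines.append(f"    {issue.detail}")
    lines.append("")
    return "\n".join(lines)


# -- bar plot ---------------------------------------------------------------

def render_plot(report: ValidationReport, chain_id: str,
                path: str | Path) -> Path:
    """Bar plot of -log10(p) per test fragment for one chain.

    One bar per window at its residue midpoint; confidently disagreeing
    fragments are drawn in a distinct colour and the decision threshold
    appears as a dashed line.  Higher bars mean lower p-values.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chain = next((c for c in report.chains if c.chain_id == chain_id), None)
    if chain is None or not chain.results:
        raise ValueError(f"no results for chain {chain_id!r}")
    thr = report.config.p_threshold
    mids, heights, colors = [], [], []
    for r in chain.results:
        nums = r.residue_numbers or list(range(r.fragment_start,
                                               r.fragment_start + r.fragment_length))
        mids.append(0.5 * (nums[0] + nums[-1]))
        heights.append(-math.log10(max(r.p_value, 1e-300)))
        outcome = classify_outcome(r, thr, chain.reference_match is not None)
        colors.append("#c0392b" if outcome == OutcomeClass.REGISTER_ERROR else "#95a5a6")
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.bar(mids, heights, width=report.config.step * 0.9, color=colors)
    ax.axhline(-math.log10(thr), linestyle="--", color="black", linewidth=1,
               label="decision threshold")
    ax.set_xlabel("residue number")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    ax.set_title(f"chain {chain_id}")
    ax.legend(loc="upper right", frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path
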