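"""Input-format sniffing and validation shared by the CLI stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["ValidationReport", "validate_fasta", "validate_sam", "validate_groups"]


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def error(self, msg: str) -> None:
        self.errors.append(msg)

    def warn(self, msg: str) -> None:
        self.warnings.append(msg)

    def extend(self, other: "ValidationReport") -> None:
        self.errors.extend(other.errors)
        self.warnings.extend(other.warnings)


def validate_fasta(path) -> ValidationReport:
    """Check FASTA structure: leading header, non-empty records, ACGTN alphabet."""
    rep = ValidationReport()
    path = Path(path)
    seen: set[str] = set()
    current = None
    n_bases = 0
    ok_chars = set("ACGTNacgtn")
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith(">"):
                    if current is not None and n_bases == 0:
                        rep.error(f"{path.name}:{lineno}: empty record {current!r}")
                    current = line[1:].split()[0]
                    if current in seen:
                        rep.error(f"{path.name}:{lineno}: duplicate id {current!r}")
                    seen.add(current)
                    n_bases = 0
                elif current is None:
                    rep.error(f"{path.name}:{lineno}: sequence before first header")
                    break
                else:
                    bad = set(line) - ok_chars
                    if bad:
                        rep.error(
                            f"{path.name}:{lineno}: unexpected characters {sorted(bad)}"
                        )
                    n_bases += len(line)
        if current is None:
            rep.error(f"{path.name}: no FASTA records found")
        elif n_bases == 0:
            rep.error(f"{path.name}: empty final record {current!r}")
    except OSError as exc:
        rep.error(f"{path}: unreadable ({exc})")
    return rep


def validate_sam(path) -> ValidationReport:
    """Check a text SAM: @SQ headers present, POS within reference bounds."""
    rep = ValidationReport()
    path = Path(path)
    lengths: dict[str, int] = {}
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("@"):
                    if line.startswith("@SQ"):
                        fields = dict(
                            f.split(":", 1) for f in line.split("\t")[1:] if ":" in f
                        )
                        if "SN" not in fields or "LN" not in fields:
                            rep.error(f"{path.name}:{lineno}: @SQ missing SN/LN")
                        else:
                            lengths[fields["SN"]] = int(fields["LN"])
                    continue
                parts = line.split("\t")
                if len(parts) < 11:
                    rep.error(f"{path.name}:{lineno}: fewer than 11 SAM fields")
                    continue
                rname, pos = parts[2], int(parts[3])
                if rname == "*":
                    continue
                if rname not in lengths:
                    rep.error(
                        f"{path.name}:{lineno}: reference {rname!r} has no @SQ header"
                    )
                elif pos > lengths[rname]:
                    rep.error(
                        f"{path.name}:{lineno}: POS {pos} beyond {rname} "
                        f"length {lengths[rname]}"
                    )
        if not lengths:
            rep.error(f"{path.name}: no @SQ header lines")
    except OSError as exc:
        rep.error(f"{path}: unreadable ({exc})")
    return rep


def validate_groups(path, universe: set[str] | None = None) -> ValidationReport:
    """Check an OrthoMCL-style groups file; warn on genomes outside a universe."""
    from .orthosets import parse_groups

    rep = ValidationReport()
    path = Path(path)
    try:
        groups = parse_groups(path.read_text())
    except (OSError, ValueError) as exc:
        rep.error(f"{path.name}: {exc}")
        return rep
    if not groups:
        rep.error(f"{path.name}: no groups found")
    if universe is not None:
        stray = sorted({g for grp in groups for g in grp.genomes} - universe)
        if stray:
            rep.warn(
                f"{path.name}: genomes not in the declared universe: {', '.join(stray)}"
            )
    return rep
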