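"""Sample-group design shared by every analysis stage.

The study design compares three uterine tissue types — normal myometrium
(NM), leiomyoma (LM, benign) and leiomyosarcoma (LMS, malignant) — plus an
optional group of LMS-derived cell lines (CELL).
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_GROUPS = ("NM", "LM", "LMS", "CELL")


class InvalidSpecError(ValueError):
    """A generator or pipeline specification violates its contract."""


@dataclass(frozen=True)
class GroupDesign:
    """Assignment of each sample to exactly one tissue group.

    Parameters
    ----------
    samples
        Mapping-like list of ``(sample_id, group)`` pairs, group one of
        NM / LM / LMS / CELL.
    """

    samples: tuple[tuple[str, str], ...]

    def __init__(self, samples) -> None:
        pairs = tuple((str(s), str(g)) for s, g in samples)
        seen: set[str] = set()
        for sid, grp in pairs:
            if grp not in VALID_GROUPS:
                raise InvalidSpecError(f"unknown group {grp!r} for sample {sid!r}")
            if sid in seen:
                raise InvalidSpecError(f"duplicate sample id {sid!r}")
            seen.add(sid)
        object.__setattr__(self, "samples", pairs)

    @classmethod
    def default(cls, n_per_group: int = 3, with_cell: bool = True) -> "GroupDesign":
        """Three samples per tissue group, optionally plus three cell lines."""
        groups = ["NM", "LM", "LMS"] + (["CELL"] if with_cell else [])
        return cls(
            [(f"{g}{i + 1}", g) for g in groups for i in range(n_per_group)]
        )

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _ in self.samples]

    def group_of(self, sample_id: str) -> str:
        for sid, grp in self.samples:
            if sid == sample_id:
                return grp
        raise KeyError(sample_id)

    def members(self, group: str) -> list[str]:
        """Sample ids belonging to ``group``."""
        if group not in VALID_GROUPS:
            raise InvalidSpecError(f"unknown group {group!r}")
        return [s for s, g in self.samples if g == group]

    @property
    def groups(self) -> list[str]:
        """Groups present, in canonical NM/LM/LMS/CELL order."""
        present = {g for _, g in self.samples}
        return [g for g in VALID_GROUPS if g in present]
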