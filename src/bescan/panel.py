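"""Base-editor targeting geometry and the bundled default editor panel.

An :class:`EditorSpec` is pure geometry: which PAM the Cas moiety requires, on
which side of the protospacer the PAM sits, how long the spacer is, and which
protospacer positions the deaminase can reach (the editing window). Protospacer
positions are always counted 5'->3' along the protospacer with position 1 at
the 5'-most base. This single convention covers both families: for a 3'-PAM
(Cas9-family) editor position 1 is the PAM-distal end, while for a 5'-PAM
(Cpf1/Cas12a-family) editor position 1 sits next to the PAM.

The default 20-editor panel ships as a tab-separated config file
(``data/editors.tsv``); that file, not code, is the source of truth, and every
entry carries the citation its geometry was transcribed from.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Union

from ._sequence import IUPAC

__all__ = [
    "PamSide",
    "CombineMode",
    "EditorSpec",
    "EditorPanel",
    "PanelError",
    "load_panel",
    "serialize_panel",
    "make_custom_editor",
]


class PanelError(ValueError):
    """Malformed editor definition or panel config."""


class PamSide(enum.Enum):
    """Side of the PAM relative to the protospacer."""

    THREE_PRIME = "three_prime"
    FIVE_PRIME = "five_prime"


class CombineMode(enum.Enum):
    UNION = "union"
    INTERSECTION = "intersection"


@dataclass(frozen=True)
class EditorSpec:
    """Targeting geometry of one base editor.

    Parameters
    ----------
    name:
        Short unique identifier, e.g. ``"BE3"``.
    pam_pattern:
        IUPAC motif the PAM must match, written 5'->3' on the protospacer
        strand (e.g. ``"NGG"``, ``"TTTV"``).
    pam_side:
        Whether the PAM is 3' (Cas9-family) or 5' (Cpf1-family) of the
        protospacer.
    spacer_length:
        Protospacer/spacer length in nt.
    window_start, window_end:
        Inclusive editing-window bounds in protospacer coordinates
        (1-based, 5'-most base = 1).
    citation:
        Free-text provenance label for the geometry.
    """

    name: str
    pam_pattern: str
    pam_side: PamSide
    spacer_length: int
    window_start: int
    window_end: int
    citation: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise PanelError("editor name must be non-empty")
        if not self.pam_pattern:
            raise PanelError(f"{self.name}: pam_pattern must be non-empty")
        bad = sorted(set(self.pam_pattern.upper()) - set(IUPAC))
        if bad:
            raise PanelError(
                f"{self.name}: pam_pattern contains non-IUPAC codes {bad!r}"
            )
        object.__setattr__(self, "pam_pattern", self.pam_pattern.upper())
        if not isinstance(self.pam_side, PamSide):
            raise PanelError(f"{self.name}: pam_side must be a PamSide")
        for fld in ("spacer_length", "window_start", "window_end"):
            v = getattr(self, fld)
            if not isinstance(v, int):
                raise PanelError(f"{self.name}: {fld} must be an integer, got {v!r}")
        if not (1 <= self.window_start <= self.window_end <= self.spacer_length):
            raise PanelError(
                f"{self.name}: require 1 <= window_start <= window_end <= "
                f"spacer_length, got window {self.window_start}..{self.window_end} "
                f"with spacer_length {self.spacer_length}"
            )

    @property
    def pam_length(self) -> int:
        return len(self.pam_pattern)

    @property
    def reach(self) -> int:
        """Maximum distance (nt) a placement extends from the target base."""
        return self.spacer_length + self.pam_length


@dataclass
class EditorPanel:
    """Ordered collection of uniquely named editors."""

    editors: tuple[EditorSpec, ...]
    combine_mode: CombineMode = CombineMode.UNION
    _by_name: dict[str, EditorSpec] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.editors = tuple(self.editors)
        if not self.editors:
            raise PanelError("panel must contain at least one editor")
        self._by_name = {}
        for ed in self.editors:
            if ed.name in self._by_name:
                raise PanelError(f"duplicate editor name {ed.name!r}")
            self._by_name[ed.name] = ed

    def __iter__(self) -> Iterator[EditorSpec]:
        return iter(self.editors)

    def __len__(self) -> int:
        return len(self.editors)

    def __getitem__(self, name: str) -> EditorSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise PanelError(
                f"unknown editor {name!r}; valid names: {', '.join(self.names)}"
            ) from None

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(ed.name for ed in self.editors)

    def subset(self, names: Iterable[str]) -> "EditorPanel":
        names = list(names)
        return EditorPanel(tuple(self[n] for n in names), self.combine_mode)


_COLUMNS = ("name", "pam_pattern", "pam_side", "spacer_length",
            "window_start", "window_end", "citation")


def _parse_row(lineno: int, fields: dict[str, str]) -> EditorSpec:
    def intfield(key: str) -> int:
        try:
            return int(fields[key])
        except ValueError:
            raise PanelError(
                f"line {lineno}: field {key!r} must be an integer, "
                f"got {fields[key]!r}"
            ) from None

    try:
        side = PamSide(fields["pam_side"])
    except ValueError:
        raise PanelError(
            f"line {lineno}: field 'pam_side' must be one of "
            f"{[s.value for s in PamSide]}, got {fields['pam_side']!r}"
        ) from None
    return EditorSpec(
        name=fields["name"],
        pam_pattern=fields["pam_pattern"],
        pam_side=side,
        spacer_length=intfield("spacer_length"),
        window_start=intfield("window_start"),
        window_end=intfield("window_end"),
        citation=fields.get("citation", ""),
    )


def load_panel(config_source: Union[str, Path, io.TextIOBase, None] = None,
               combine_mode: CombineMode = CombineMode.UNION) -> EditorPanel:
    """Load an editor panel from a TSV config (default: the bundled panel).

    The config is tab-separated with a header row naming the columns
    ``name pam_pattern pam_side spacer_length window_start window_end
    citation``; ``#`` lines are comments.
    """
    if config_source is None:
        text = (resources.files("bescan") / "data" / "editors.tsv").read_text()
    elif isinstance(config_source, (str, Path)):
        text = Path(config_source).read_text()
    else:
        text = config_source.read()

    header: list[str] | None = None
    editors: list[EditorSpec] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = [p.strip() for p in parts]
            missing = [c for c in _COLUMNS[:-1] if c not in header]
            if missing:
                raise PanelError(f"config header missing columns {missing}")
            continue
        if len(parts) < len(header):
            parts += [""] * (len(header) - len(parts))
        fields = dict(zip(header, (p.strip() for p in parts)))
        editors.append(_parse_row(lineno, fields))
    if header is None:
        raise PanelError("empty panel config")
    return EditorPanel(tuple(editors), combine_mode)


def serialize_panel(panel: EditorPanel) -> str:
    """Serialize a panel to the TSV dialect accepted by :func:`load_panel`."""
    lines = ["\t".join(_COLUMNS)]
    for ed in panel:
        lines.append("\t".join([
            ed.name, ed.pam_pattern, ed.pam_side.value, str(ed.spacer_length),
            str(ed.window_start), str(ed.window_end), ed.citation,
        ]))
    return "\n".join(lines) + "\n"


def make_custom_editor(pam_pattern: str,
                       pam_side: Union[PamSide, str],
                       spacer_length: int,
                       window_start: int,
                       window_end: int,
                       name: str = "custom",
                       citation: str = "user-defined") -> EditorSpec:
    """Build a validated user-defined editor spec.

    Accepts ``pam_side`` as a :class:`PamSide` or its string value
    (``"three_prime"`` / ``"five_prime"``).
    """
    if not isinstance(pam_side, PamSide):
        try:
            pam_side = PamSide(pam_side)
        except ValueError:
            raise PanelError(
                f"pam_side must be one of {[s.value for s in PamSide]}, "
                f"got {pam_side!r}"
            ) from None
    return EditorSpec(name=name, pam_pattern=pam_pattern, pam_side=pam_side,
                      spacer_length=spacer_length, window_start=window_start,
                      window_end=window_end, citation=citation)


def default_panel() -> EditorPanel:
    """The bundled 20-editor panel."""
    return load_panel(None)
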