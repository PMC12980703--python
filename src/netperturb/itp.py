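"""GROMACS-dialect topology-include (.itp) I/O for interaction networks.

Two dialects are understood, matching what standard Martini tooling emits:

* **Elastic network**: a ``[ bonds ]`` section whose data lines read
  ``i  j  funct  r0  kappa`` with ``funct == 1`` (harmonic), 1-based bead
  indices, r0 in nm and kappa in kJ/mol/nm^2.

* **Go-type contacts**: an ``[ atomtypes ]`` section declaring per-bead
  virtual-site types whose names end in ``_<index>`` (1-based bead index,
  e.g. ``mol_A_17``), plus a ``[ nonbond_params ]`` section with lines
  ``name_i  name_j  1  sigma  epsilon`` (sigma in nm, epsilon in kJ/mol).

The reader returns the extracted network together with an opaque
:class:`ItpDocument` that retains every byte of the input.  The writer
rewrites *only* the numeric strength (and, when refitted, geometry) fields in
place — same line, same token slot, same decimal count, right-aligned to the
original column width when it fits — so a write with an unchanged network is
byte-identical to the input, and unknown sections always pass through
untouched.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .networks import ENM_HARMONIC, GO_LJ, Contact, InteractionNetwork

__all__ = ["ItpDocument", "read_itp", "write_itp"]

_SECTION_RE = re.compile(r"^\s*\[\s*([A-Za-z0-9_-]+)\s*\]")
_TOKEN_RE = re.compile(r"\S+")
_TYPE_INDEX_RE = re.compile(r"_(\d+)$")


@dataclass
class _Record:
    """Location of one contact's editable numeric fields inside the document."""

    pair: tuple[int, int]  # 0-based, i < j
    line_idx: int
    geometry_span: tuple[int, int]
    strength_span: tuple[int, int]
    geometry: float
    strength: float


@dataclass
class ItpDocument:
    """Verbatim .itp content plus the parsed contact-field locations."""

    lines: list[str]  # with line terminators preserved
    kind: str
    records: list[_Record] = field(default_factory=list)

    def text(self) -> str:
        return "".join(self.lines)


def _strip_comment(line: str) -> str:
    return line.split(";", 1)[0]


def _data_tokens(line: str):
    """Non-comment tokens of a line with their character spans."""
    payload = _strip_comment(line)
    return [(m.group(0), m.span()) for m in _TOKEN_RE.finditer(payload)]


def _parse_float(token: str, path, lineno: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ValueError(
            f"{path}:{lineno}: malformed numeric field for {what}: {token!r}"
        ) from None


def _bead_index_from_type(name: str, path, lineno: int) -> int:
    m = _TYPE_INDEX_RE.search(name)
    if m is None:
        raise ValueError(
            f"{path}:{lineno}: atom-type name {name!r} does not end in _<index>; "
            "cannot map it to a bead"
        )
    return int(m.group(1)) - 1


def read_itp(path) -> tuple[InteractionNetwork, ItpDocument]:
    """Parse an .itp fragment into a network plus its verbatim document.

    Recognizes either an elastic ``[ bonds ]`` network or a Go-type
    ``[ atomtypes ]`` + ``[ nonbond_params ]`` pair table; raises when neither
    section is present, on malformed numbers and on duplicate pairs.
    """
    with open(path, newline="") as fh:
        raw = fh.read()
    lines = raw.splitlines(keepends=True)

    sections: dict[str, list[int]] = {}
    current = None
    for idx, line in enumerate(lines):
        m = _SECTION_RE.match(line)
        if m:
            current = m.group(1).lower()
            sections.setdefault(current, [])
            continue
        if current is not None and _data_tokens(line):
            sections[current].append(idx)

    if "bonds" in sections and sections["bonds"]:
        kind = ENM_HARMONIC
        records = _parse_bonds(lines, sections["bonds"], path)
    elif "nonbond_params" in sections and sections["nonbond_params"]:
        if "atomtypes" not in sections:
            raise ValueError(
                f"{path}: [ nonbond_params ] present but required section "
                "[ atomtypes ] is missing"
            )
        kind = GO_LJ
        records = _parse_nonbond(lines, sections["nonbond_params"], path)
    else:
        raise ValueError(
            f"{path}: no recognized network section found "
            "(need [ bonds ] or [ nonbond_params ] with [ atomtypes ])"
        )

    seen = set()
    for rec in records:
        if rec.pair in seen:
            raise ValueError(f"{path}: duplicate pair entry {rec.pair}")
        seen.add(rec.pair)

    n_beads = max(max(p) for p in seen) + 1
    if "atoms" in sections:
        n_beads = max(n_beads, len(sections["atoms"]))
    contacts = [
        Contact(rec.pair[0], rec.pair[1], kind, rec.strength, rec.geometry)
        for rec in records
    ]
    network = InteractionNetwork(contacts, n_beads, kind)
    return network, ItpDocument(lines=lines, kind=kind, records=records)


def _parse_bonds(lines, data_idx, path) -> list[_Record]:
    records = []
    for idx in data_idx:
        toks = _data_tokens(lines[idx])
        if len(toks) < 5:
            raise ValueError(
                f"{path}:{idx + 1}: [ bonds ] line needs 'i j funct r0 kappa'"
            )
        i = int(_parse_float(toks[0][0], path, idx + 1, "bead i")) - 1
        j = int(_parse_float(toks[1][0], path, idx + 1, "bead j")) - 1
        funct = toks[2][0]
        if funct != "1":
            raise ValueError(
                f"{path}:{idx + 1}: unsupported bond function type {funct!r} "
                "(only harmonic type 1)"
            )
        r0 = _parse_float(toks[3][0], path, idx + 1, "r0")
        kappa = _parse_float(toks[4][0], path, idx + 1, "kappa")
        pair = (min(i, j), max(i, j))
        records.append(_Record(pair, idx, toks[3][1], toks[4][1], r0, kappa))
    return records


def _parse_nonbond(lines, data_idx, path) -> list[_Record]:
    records = []
    for idx in data_idx:
        toks = _data_tokens(lines[idx])
        if len(toks) < 5:
            raise ValueError(
                f"{path}:{idx + 1}: [ nonbond_params ] line needs "
                "'type_i type_j 1 sigma epsilon'"
            )
        i = _bead_index_from_type(toks[0][0], path, idx + 1)
        j = _bead_index_from_type(toks[1][0], path, idx + 1)
        sigma = _parse_float(toks[3][0], path, idx + 1, "sigma")
        epsilon = _parse_float(toks[4][0], path, idx + 1, "epsilon")
        pair = (min(i, j), max(i, j))
        records.append(_Record(pair, idx, toks[3][1], toks[4][1], sigma, epsilon))
    return records


def _format_like(value: float, original_token: str) -> str:
    """Render ``value`` mimicking the original token's decimal count and width."""
    if value == float(original_token):
        return original_token
    if "e" in original_token.lower():
        formatted = f"{value:.{len(original_token)}g}"
    else:
        decimals = len(original_token.partition(".")[2])
        formatted = f"{value:.{decimals}f}"
        if float(formatted) != value:  # value needs more digits than the column had
            formatted = f"{value:.10g}"
    if len(formatted) < len(original_token):
        formatted = formatted.rjust(len(original_token))
    return formatted


def write_itp(document: ItpDocument, network: InteractionNetwork, path) -> None:
    """Write the document with the network's strengths/geometries spliced in.

    Every byte outside the edited numeric fields is preserved; a network whose
    values equal the parsed ones round-trips byte-identically.  A contact pair
    absent from the document is an error (the topology is fixed).
    """
    if network.kind != document.kind:
        raise ValueError(
            f"network kind {network.kind!r} does not match document kind {document.kind!r}"
        )
    by_pair = {rec.pair: rec for rec in document.records}
    missing = [(c.i, c.j) for c in network.contacts if (c.i, c.j) not in by_pair]
    if missing:
        raise ValueError(f"network pairs absent from the document: {missing[:5]}")
    if network.n_contacts != len(document.records):
        raise ValueError(
            f"network has {network.n_contacts} contacts, document has "
            f"{len(document.records)}; the pair lists must match"
        )

    lines = list(document.lines)
    # group edits per line, apply right-to-left so spans stay valid
    edits: dict[int, list[tuple[tuple[int, int], str]]] = {}
    for contact in network.contacts:
        rec = by_pair[(contact.i, contact.j)]
        line = lines[rec.line_idx]
        for span, value in ((rec.geometry_span, contact.geometry),
                            (rec.strength_span, contact.strength)):
            original = line[span[0]:span[1]]
            edits.setdefault(rec.line_idx, []).append((span, _format_like(value, original)))
    for line_idx, line_edits in edits.items():
        line = lines[line_idx]
        for (start, stop), replacement in sorted(line_edits, reverse=True):
            line = line[:start] + replacement + line[stop:]
        lines[line_idx] = line

    with open(path, "w", newline="") as fh:
        fh.write("".join(lines))
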