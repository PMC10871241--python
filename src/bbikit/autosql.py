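"""autoSql schema parsing and emission.

autoSql is UCSC's small schema language describing the typed columns of a
BED+ record; BigBed files can embed one schema as a NUL-terminated string.
Only the ``table`` form is supported, which is the only form that appears
in BigBed files:

    table bed3
    "Browser extensible data"
    (
    string chrom;      "Reference sequence chromosome or scaffold"
    uint   chromStart; "Start position in chromosome"
    uint   chromEnd;   "End position in chromosome"
    )

Type tokens (``uint``, ``string``, ``char[2]``, ...) are kept verbatim; no
type checking is performed against field contents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParseError, ValidationError

# column names of the 12 defined BED fields, used for generated schemas
BED_FIELD_DEFS: list[tuple[str, str, str]] = [
    ("string", "chrom", "Reference sequence chromosome or scaffold"),
    ("uint", "chromStart", "Start position in chromosome"),
    ("uint", "chromEnd", "End position in chromosome"),
    ("string", "name", "Name of item"),
    ("uint", "score", "Score from 0-1000"),
    ("char[1]", "strand", "+ or -"),
    ("uint", "thickStart", "Start of where display should be thick"),
    ("uint", "thickEnd", "End of where display should be thick"),
    ("uint", "reserved", "Used as itemRgb"),
    ("int", "blockCount", "Number of blocks"),
    ("int[blockCount]", "blockSizes", "Size of each block"),
    ("int[blockCount]", "chromStarts", "Start of each block relative to chromStart"),
]


@dataclass(frozen=True, slots=True)
class AutoSqlField:
    type: str
    name: str
    comment: str


@dataclass(frozen=True)
class AutoSqlSchema:
    name: str
    comment: str
    fields: tuple[AutoSqlField, ...] = field(default=())

    def __post_init__(self):
        names = [f.name for f in self.fields]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate field names in schema {self.name!r}")
        if len(names) < 3:
            raise ValidationError(
                f"schema {self.name!r} has {len(names)} fields; at least 3 "
                "(chrom, start, end) are required"
            )

    @property
    def field_count(self) -> int:
        return len(self.fields)


class _Scanner:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, msg: str) -> ParseError:
        return ParseError(msg, offset=self.pos)

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def eof(self) -> bool:
        self.skip_ws()
        return self.pos >= len(self.text)

    def peek(self) -> str:
        self.skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def expect(self, ch: str) -> None:
        if self.peek() != ch:
            raise self.error(f"expected {ch!r}")
        self.pos += 1

    def word(self) -> str:
        """A run of non-space characters stopping before ; ( ) and quotes."""
        self.skip_ws()
        start = self.pos
        while self.pos < len(self.text):
            c = self.text[self.pos]
            if c.isspace() or c in ';()"':
                break
            self.pos += 1
        if self.pos == start:
            raise self.error("expected a token")
        return self.text[start : self.pos]

    def quoted(self) -> str:
        self.expect('"')
        start = self.pos
        end = self.text.find('"', start)
        if end < 0:
            self.pos = start - 1
            raise self.error("unbalanced quote")
        self.pos = end + 1
        return self.text[start:end]


def parse_autosql(text: str) -> AutoSqlSchema:
    """Parse one autoSql ``table`` declaration."""
    sc = _Scanner(text)
    kw = sc.word()
    if kw != "table":
        raise sc.error(f"expected 'table', got {kw!r}")
    name = sc.word()
    comment = sc.quoted()
    sc.expect("(")
    fields: list[AutoSqlField] = []
    while True:
        if sc.eof():
            raise sc.error("unbalanced parenthesis: missing ')'")
        if sc.peek() == ")":
            sc.pos += 1
            break
        tokens: list[str] = []
        while sc.peek() not in (";", ""):
            if sc.peek() in ')("':
                raise sc.error("expected ';' terminating field declaration")
            tokens.append(sc.word())
        if sc.peek() != ";":
            raise sc.error("expected ';' terminating field declaration")
        sc.pos += 1
        if len(tokens) < 2:
            raise sc.error("field declaration needs a type and a name")
        fields.append(
            AutoSqlField(" ".join(tokens[:-1]), tokens[-1], sc.quoted())
        )
    return AutoSqlSchema(name, comment, tuple(fields))


def emit_autosql(schema: AutoSqlSchema) -> str:
    """Render a schema back to autoSql text; reparsing yields an equal schema."""
    width = max(len(f.type) for f in schema.fields)
    lines = [f"table {schema.name}", f'"{schema.comment}"', "("]
    for f in schema.fields:
        lines.append(f'    {f.type.ljust(width)} {f.name}; "{f.comment}"')
    lines.append(")")
    return "\n".join(lines) + "\n"


def bed_schema(field_count: int, defined_field_count: int | None = None) -> AutoSqlSchema:
    """A generated schema for a plain bedN[+P] table.

    The first ``defined_field_count`` columns (capped at the 12 standard BED
    fields) take their standard names; any extra columns become
    ``string field<i>``.
    """
    if field_count < 3:
        raise ValidationError("BED needs at least 3 fields")
    defined = min(defined_field_count if defined_field_count is not None else field_count, 12)
    if defined > field_count:
        raise ValidationError(
            f"defined field count {defined} exceeds field count {field_count}"
        )
    fields = [AutoSqlField(*BED_FIELD_DEFS[i]) for i in range(defined)]
    for i in range(defined, field_count):
        fields.append(AutoSqlField("string", f"field{i + 1}", "Undefined field"))
    plus = f"+{field_count - defined}" if field_count > defined else ""
    return AutoSqlSchema(f"bed{defined}{plus}", "Browser Extensible Data", tuple(fields))
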