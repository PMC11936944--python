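"""Gene-set (module) definitions and GMT input/output.

A module is a named set of co-expressed genes; in the BloodGen3 repertoire
modules carry ids like ``M12.15`` and belong to higher-level aggregates like
``A27``.  Modules are exchanged in the GMT format: one tab-separated line per
set — name, description, then member gene symbols.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from modmarker.errors import SchemaError, ValidationError


@dataclass(frozen=True)
class ModuleDefinition:
    module_id: str
    genes: tuple[str, ...]
    aggregate_id: str | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"module {self.module_id} has no genes")
        upper = tuple(g.upper() for g in self.genes)
        if len(set(upper)) != len(upper):
            dups = sorted({g for g in upper if upper.count(g) > 1})
            raise ValidationError(f"module {self.module_id} has duplicate genes: {dups}")
        object.__setattr__(self, "genes", upper)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes


def read_gmt(path: str | Path) -> list[ModuleDefinition]:
    """Parse a GMT file into module definitions.

    The description field is kept as the aggregate label when non-empty.
    """
    modules = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise SchemaError(
                f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
            )
        name, description, *genes = fields
        genes = [g for g in genes if g.strip()]
        modules.append(
            ModuleDefinition(
                module_id=name,
                genes=tuple(genes),
                aggregate_id=description.strip() or None,
            )
        )
    if not modules:
        raise SchemaError(f"{path}: empty GMT file")
    return modules


def write_gmt(modules: list[ModuleDefinition] | ModuleDefinition, path: str | Path) -> None:
    if isinstance(modules, ModuleDefinition):
        modules = [modules]
    lines = [
        "\t".join([m.module_id, m.aggregate_id or ""] + list(m.genes)) for m in modules
    ]
    Path(path).write_text("\n".join(lines) + "\n")
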