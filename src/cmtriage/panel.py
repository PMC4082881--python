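"""The 51-gene inherited-neuropathy panel.

Each gene carries its reference transcript, the neuropathy phenotypes it is
associated with, its inheritance modes, and a category: ``cmt_gene`` for
genes causing a form of Charcot-Marie-Tooth disease proper, or
``other_neuropathy_gene`` for genes causing overlapping conditions (distal
hereditary motor neuropathy, HSAN, hereditary neuralgic amyotrophy, ...).

The category is derived from the phenotype codes: any gene whose phenotype
set intersects the CMT spectrum (CMT1, CMT2, CMT4, CMTX, intermediate CMT,
Dejerine-Sottas, HNPP) is a CMT gene.  A per-gene ``category_override`` in
the config can re-map borderline genes; the packaged default uses it for
GAN and SLC12A6, whose phenotypes (giant axonal neuropathy, ACCPN) are
severe hereditary motor-and-sensory neuropathies conventionally counted
within the CMT spectrum, giving the default panel its 32 CMT / 19 other
split.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

import yaml

from .models import ConfigurationError, Inheritance


class GeneCategory(str, enum.Enum):
    CMT_GENE = "cmt_gene"
    OTHER_NEUROPATHY_GENE = "other_neuropathy_gene"


#: phenotype codes counted as CMT proper
CMT_PHENOTYPES = frozenset({"CMT1", "CMT2", "CMT4", "CMTX", "ICMT", "DSN", "HNPP"})

#: all phenotype codes the panel config may use
VALID_PHENOTYPES = CMT_PHENOTYPES | frozenset(
    {
        "dHMN",
        "HSAN",
        "GAN",
        "HNA",
        "ACCPN",
        "CCFDN",
        "PCWH",
        "slow-NCV",
        "CMT-associated",
    }
)

_INHERITANCE_TOKENS = {
    "autosomal_dominant": Inheritance.AUTOSOMAL_DOMINANT,
    "autosomal_recessive": Inheritance.AUTOSOMAL_RECESSIVE,
    "x_linked": Inheritance.X_LINKED,
}


@dataclass(frozen=True)
class GeneRecord:
    symbol: str
    transcript: str
    phenotypes: frozenset[str]
    inheritance_modes: frozenset[Inheritance]
    category: GeneCategory

    def __post_init__(self) -> None:
        if not self.phenotypes:
            raise ConfigurationError(f"{self.symbol}: at least one phenotype required")
        if not self.inheritance_modes:
            raise ConfigurationError(
                f"{self.symbol}: at least one inheritance mode required"
            )
        unknown = self.phenotypes - VALID_PHENOTYPES
        if unknown:
            raise ConfigurationError(
                f"{self.symbol}: unknown phenotype codes {sorted(unknown)}"
            )

    @property
    def recessive_only(self) -> bool:
        return self.inheritance_modes == frozenset({Inheritance.AUTOSOMAL_RECESSIVE})

    @property
    def x_linked(self) -> bool:
        return Inheritance.X_LINKED in self.inheritance_modes


@dataclass
class PanelConfig:
    genes: tuple[GeneRecord, ...]
    region_padding_bp: int = 10
    include_utr: bool = True
    _by_symbol: dict[str, GeneRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ConfigurationError("panel must contain at least one gene")
        if self.region_padding_bp < 0:
            raise ConfigurationError("region_padding_bp must be >= 0")
        self._by_symbol = {}
        for g in self.genes:
            if g.symbol in self._by_symbol:
                raise ConfigurationError(f"duplicate gene symbol {g.symbol!r}")
            self._by_symbol[g.symbol] = g

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, symbol: str) -> GeneRecord:
        try:
            return self._by_symbol[symbol]
        except KeyError:
            raise ConfigurationError(f"gene {symbol!r} is not on the panel") from None

    def symbols(self) -> list[str]:
        return [g.symbol for g in self.genes]

    def category_counts(self) -> dict[GeneCategory, int]:
        counts = {cat: 0 for cat in GeneCategory}
        for g in self.genes:
            counts[g.category] += 1
        return counts


def _derive_category(phenotypes: Iterable[str], override: str | None) -> GeneCategory:
    if override is not None:
        try:
            return GeneCategory(override)
        except ValueError:
            raise ConfigurationError(f"unknown category override {override!r}") from None
    if set(phenotypes) & CMT_PHENOTYPES:
        return GeneCategory.CMT_GENE
    return GeneCategory.OTHER_NEUROPATHY_GENE


def load_panel(source: Union[str, Path, dict]) -> PanelConfig:
    """Load and validate a panel configuration from YAML (path or dict).

    The config has a ``genes`` list (fields: ``symbol``, ``transcript``,
    ``phenotypes``, ``inheritance``, optional ``category_override``) plus
    optional ``region_padding_bp`` and ``include_utr``.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = source
    if not isinstance(cfg, dict) or "genes" not in cfg:
        raise ConfigurationError("panel config must be a mapping with a 'genes' list")
    records = []
    for entry in cfg["genes"]:
        try:
            modes = frozenset(_INHERITANCE_TOKENS[t] for t in entry["inheritance"])
        except KeyError as exc:
            raise ConfigurationError(
                f"{entry.get('symbol', '?')}: bad inheritance token {exc}"
            ) from None
        phenotypes = frozenset(entry["phenotypes"])
        records.append(
            GeneRecord(
                symbol=entry["symbol"],
                transcript=entry.get("transcript", ""),
                phenotypes=phenotypes,
                inheritance_modes=modes,
                category=_derive_category(phenotypes, entry.get("category_override")),
            )
        )
    return PanelConfig(
        genes=tuple(records),
        region_padding_bp=int(cfg.get("region_padding_bp", 10)),
        include_utr=bool(cfg.get("include_utr", True)),
    )


def serialize_panel(panel: PanelConfig) -> dict:
    """Inverse of :func:`load_panel` (round-trips exactly)."""
    genes = []
    for g in panel.genes:
        entry = {
            "symbol": g.symbol,
            "transcript": g.transcript,
            "phenotypes": sorted(g.phenotypes),
            "inheritance": sorted(m.value for m in g.inheritance_modes),
        }
        if g.category != _derive_category(g.phenotypes, None):
            entry["category_override"] = g.category.value
        genes.append(entry)
    return {
        "genes": genes,
        "region_padding_bp": panel.region_padding_bp,
        "include_utr": panel.include_utr,
    }


def default_panel() -> PanelConfig:
    """The packaged default 51-gene panel."""
    ref = resources.files("cmtriage.data") / "panel.yaml"
    with resources.as_file(ref) as path:
        return load_panel(path)


def gene_category(panel: PanelConfig, gene: Union[str, GeneRecord]) -> GeneCategory:
    """Category of a panel gene; raises ConfigurationError if off-panel."""
    symbol = gene if isinstance(gene, str) else gene.symbol
    return panel.gene(symbol).category
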