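"""Substrate and stereochemistry registries, loaded from the packaged data
files so that chemistry is auditable and editable without code changes."""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .errors import RegistryError


def _load_data(name: str) -> dict:
    ref = resources.files("pksdesign").joinpath("data", name)
    return json.loads(ref.read_text(encoding="utf-8"))


@dataclass(frozen=True)
class StarterUnit:
    """A loading-module substrate; ``acyl_smiles`` is the acyl group already
    capped as its thioacid thioester surrogate (``C(=O)S``)."""

    name: str
    acyl_smiles: str


@dataclass(frozen=True)
class ExtenderUnit:
    """A malonyl-CoA analog; ``alpha_substituent_smiles`` is the R' branch
    installed at the new alpha carbon ('' means hydrogen)."""

    name: str
    alpha_substituent_smiles: str


@dataclass(frozen=True)
class KrStereoRule:
    """Outcome of one KR type: whether it reduces the beta-ketone, and the
    CIP descriptors targeted at the beta and alpha carbons (None = leave
    unspecified / untouched)."""

    kr_type: str
    reduces: bool
    beta_cip: str | None
    alpha_cip: str | None


class Registry(dict):
    """Name -> unit mapping with a helpful lookup error."""

    def __init__(self, label: str, items: dict):
        super().__init__(items)
        self.label = label

    def get_unit(self, name: str):
        try:
            return self[name]
        except KeyError:
            known = ", ".join(sorted(self))
            raise RegistryError(
                f"unknown {self.label} {name!r}; known: {known}") from None


@lru_cache(maxsize=1)
def default_starters() -> Registry:
    doc = _load_data("starters.json")
    return Registry("starter", {
        name: StarterUnit(name, smi)
        for name, smi in doc["starters"].items()})


@lru_cache(maxsize=1)
def default_extenders() -> Registry:
    doc = _load_data("extenders.json")
    return Registry("extender", {
        name: ExtenderUnit(name, frag)
        for name, frag in doc["extenders"].items()})


@lru_cache(maxsize=1)
def kr_stereo_rules() -> Registry:
    doc = _load_data("kr_stereo.json")
    return Registry("KR type", {
        name: KrStereoRule(name, entry["reduces"], entry.get("beta_cip"),
                           entry.get("alpha_cip"))
        for name, entry in doc["types"].items()})


@lru_cache(maxsize=1)
def reaction_operators() -> dict[str, str]:
    return dict(_load_data("operators.json")["operators"])
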