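"""Readers and writers for the package's plain-text formats.

* Networks: YAML with a ``compounds`` block (formula string, charge,
  dGf0') and a ``reactions`` block (catabolic/anabolic stoichiometry
  maps, lambda, population bin, scenario, chain).
* Media and conversion vectors: two-column TSV (compound, value) with
  ``# key: value`` metadata comments (dilution rate, biomass rate).
* Count tables: TSV with orf_id, bin_id, length, count[, family].

Loaders aim for round-trip fidelity: load(save(x)) reproduces x.
Malformed lines raise errors naming the file and line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import pandas as pd
import yaml

from .network import Network
from .omics import REQUIRED_COLUMNS, validate_count_table
from .stoichiometry import (
    Compound,
    ConversionVector,
    HalfReaction,
    Medium,
    MetabolicReaction,
    Registry,
    StoichiometryError,
    format_formula,
    parse_formula,
)

PathLike = Union[str, Path]


class FormatError(ValueError):
    pass


# -- networks ---------------------------------------------------------------


def network_to_dict(network: Network) -> dict:
    compounds = {}
    for comp in network.registry.values():
        entry = {
            "formula": format_formula(comp.formula),
            "charge": float(comp.charge),
        }
        if comp.dGf0_prime is not None:
            entry["dGf0"] = float(comp.dGf0_prime)
        if comp.roles:
            entry["roles"] = list(comp.roles)
        if comp.mean_chain_length is not None:
            entry["mean_chain_length"] = float(comp.mean_chain_length)
        if comp.note:
            entry["note"] = comp.note
        compounds[comp.id] = entry
    reactions = []
    for rxn in network.reactions:
        entry = {
            "id": rxn.id,
            "population": rxn.population,
            "scenario": rxn.scenario,
            "lambda": float(rxn.lambda_cat),
            "yield": float(rxn.yield_Y),
            "catabolic": {c: float(k) for c, k in rxn.catabolic.stoich.items()},
        }
        if rxn.anabolic is not None:
            entry["anabolic"] = {c: float(k) for c, k in rxn.anabolic.stoich.items()}
        if rxn.chain:
            entry["chain"] = rxn.chain
        if rxn.note:
            entry["note"] = rxn.note
        reactions.append(entry)
    return {"compounds": compounds, "reactions": reactions}


def save_network(network: Network, path: PathLike) -> None:
    Path(path).write_text(
        yaml.safe_dump(network_to_dict(network), sort_keys=False, width=100)
    )


def network_from_dict(data: dict) -> Network:
    if "compounds" not in data or "reactions" not in data:
        raise FormatError("network file needs 'compounds' and 'reactions' blocks")
    reg = Registry()
    for cid, entry in data["compounds"].items():
        reg.add(
            Compound(
                id=cid,
                formula=parse_formula(entry.get("formula", "")),
                charge=float(entry.get("charge", 0.0)),
                dGf0_prime=entry.get("dGf0"),
                roles=tuple(entry.get("roles", ())),
                mean_chain_length=entry.get("mean_chain_length"),
                note=entry.get("note", ""),
            )
        )
    reactions = []
    for entry in data["reactions"]:
        try:
            rid = entry["id"]
            cat = HalfReaction(dict(entry["catabolic"]), "catabolic")
        except KeyError as exc:
            raise FormatError(f"reaction entry missing field {exc}") from None
        an = (
            HalfReaction(dict(entry["anabolic"]), "anabolic")
            if "anabolic" in entry
            else None
        )
        for half in ([cat.stoich] + ([an.stoich] if an else [])):
            for cid in half:
                reg[cid]  # raises naming the compound if unknown
        reactions.append(
            MetabolicReaction(
                id=rid,
                catabolic=cat,
                anabolic=an,
                lambda_cat=float(entry.get("lambda", 1.0)),
                population=entry.get("population", ""),
                scenario=entry.get("scenario", "both"),
                yield_Y=float(entry.get("yield", 0.0)),
                chain=entry.get("chain"),
                note=entry.get("note", ""),
            )
        )
    return Network(registry=reg, reactions=reactions)


def load_network(path: PathLike) -> Network:
    """Load a network; unbalanced reactions are reported by
    ``Network.validate()``, not rejected here."""
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"{path}: not valid YAML: {exc}") from None
    return network_from_dict(data)


# -- two-column tables ------------------------------------------------------


def _read_two_column(path: PathLike) -> Tuple[Dict[str, float], Dict[str, float]]:
    values: Dict[str, float] = {}
    meta: Dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                try:
                    meta[key.strip()] = float(val)
                except ValueError:
                    pass
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(
                f"{path}:{lineno}: expected two tab-separated columns, got {len(parts)}"
            )
        name, val = parts
        if name in values:
            raise FormatError(f"{path}:{lineno}: duplicate entry {name!r}")
        try:
            values[name] = float(val)
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: cannot parse value {val!r}"
            ) from None
    return values, meta


def load_medium(path: PathLike, dilution_rate: Optional[float] = None) -> Medium:
    values, meta = _read_two_column(path)
    rate = dilution_rate if dilution_rate is not None else meta.get("dilution_rate")
    if rate is None:
        raise FormatError(
            f"{path}: no '# dilution_rate:' metadata and none given"
        )
    return Medium(values, rate)


def save_medium(medium: Medium, path: PathLike) -> None:
    lines = [f"# dilution_rate: {medium.dilution_rate!r}"]
    lines += [f"{cid}\t{conc!r}" for cid, conc in medium.concentrations.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def load_conversions(path: PathLike) -> ConversionVector:
    values, meta = _read_two_column(path)
    biomass = values.pop("biomass", meta.get("biomass_rate", 0.0))
    return ConversionVector(values, biomass_rate=biomass)


def save_conversions(vec: ConversionVector, path: PathLike) -> None:
    lines = [f"# biomass_rate: {vec.biomass_rate!r}"]
    lines += [f"{cid}\t{rate!r}" for cid, rate in vec.rates.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# -- count tables -----------------------------------------------------------


def load_counts(path: PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    try:
        return validate_count_table(table)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def save_counts(table: pd.DataFrame, path: PathLike) -> None:
    table.to_csv(path, sep="\t", index=False)


# -- fit reports ------------------------------------------------------------


def write_report(result, prefix: PathLike) -> Tuple[Path, Path]:
    """Write a CommunityFitResults as JSON (summary quantities) plus a TSV
    flux table.  Returns the two paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "scenario": result.model.scenario,
        "residual_norm": result.residual_norm,
        "community_yield": result.community_yield,
        "biomass_rate": result.modeled.biomass_rate,
        "carbon_consumed": result.carbon_consumed(),
        "storage_rate": result.storage_rate,
        "abundances": result.abundances,
        "rates": result.rates,
        "modeled_conversions": result.modeled.rates,
    }
    json_path = Path(str(prefix) + ".json")
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    rows = []
    for rxn in result.model.reactions:
        rows.append(
            {
                "reaction": rxn.id,
                "population": rxn.population,
                "rate_mmol_l_day": result.rates[rxn.id],
                "yield_Y": rxn.yield_Y,
                "chain": rxn.chain or "-",
            }
        )
    tsv_path = Path(str(prefix) + ".fluxes.tsv")
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    return json_path, tsv_path
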