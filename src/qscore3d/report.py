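"""Structured validation reports and attribute-file export.

A :class:`ValidationReport` collects every number the pipeline produces for
one map/model pair — model-average Q, group tables, the classification
against the archive statistical model, percentile ranks and the B-factor
scan summary — into one JSON-serialisable document.  Attribute files use the
ChimeraX ``defattr`` format so per-atom/per-residue Q can be loaded for
colour-coding without this package rendering anything itself.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

from .groups import groups_frame
from .percentiles import RelativeScores
from .resstats import Classification

SCHEMA_VERSION = "1.0"


@dataclass
class ValidationReport:
    model_average_q: float
    n_atoms_scored: int
    n_atoms_undefined: int
    resolution: float | None = None
    classification: Classification | None = None
    relative: RelativeScores | None = None
    advisory: str | None = None
    f_opt: float | None = None
    cc_at_f_opt: float | None = None
    params: dict | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        out = {"schema_version": SCHEMA_VERSION}
        for key, value in asdict(self).items():
            out[key] = value
        return out

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def report_from_pipeline(
    table,
    classification=None,
    relative=None,
    advisory=None,
    scan=None,
    resolution=None,
    seed=None,
) -> ValidationReport:
    """Assemble a report from pipeline outputs (any optional part may be None)."""
    q = table.q_values
    import numpy as np

    defined = np.isfinite(q)
    cc = None
    if scan is not None:
        cc = float(scan.cc_values[int(np.argmax(scan.cc_values))])
    return ValidationReport(
        model_average_q=table.model_average,
        n_atoms_scored=int(defined.sum()),
        n_atoms_undefined=int((~defined).sum()),
        resolution=resolution,
        classification=classification,
        relative=relative,
        advisory=advisory,
        f_opt=None if scan is None else scan.f_opt,
        cc_at_f_opt=cc,
        params={
            "sigma_ref": table.params.sigma_ref,
            "max_radius": table.params.max_radius,
            "radial_step": table.params.radial_step,
            "points_per_shell": table.params.points_per_shell,
            "min_points": table.params.min_points,
        },
        seed=seed,
    )


def _atom_spec(chain, resnum, atom=None) -> str:
    spec = f"/{chain}:{resnum}"
    return spec if atom is None else f"{spec}@{atom}"


def write_atom_attributes(table, path, attribute: str = "qscore") -> None:
    """Per-atom Q as a ChimeraX defattr file (undefined atoms omitted)."""
    with open(path, "w") as fh:
        fh.write(f"attribute: {attribute}\nrecipient: atoms\n")
        for e in table:
            if e.defined:
                fh.write(f"\t{_atom_spec(e.atom.chain, e.atom.res_seq, e.atom.atom_name)}\t{e.q:.4f}\n")


def write_group_attributes(groups, path, attribute: str = "qscore_residue",
                           partition: str = "whole") -> None:
    """Per-residue group Q as a ChimeraX defattr file (one partition)."""
    with open(path, "w") as fh:
        fh.write(f"attribute: {attribute}\nrecipient: residues\n")
        for g in groups:
            if g.partition == partition:
                fh.write(f"\t{_atom_spec(g.chain, g.res_seq)}\t{g.q_mean:.4f}\n")


def write_group_table(groups, path) -> None:
    groups_frame(groups).to_csv(path, sep="\t", index=False)
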