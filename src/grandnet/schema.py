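"""Versioned structural schema for the JSON reports the CLI writes."""

from __future__ import annotations

REPORT_SCHEMA_VERSION = 1

# field name -> (required, type check)
_NUMBER = (int, float)
REPORT_FIELDS: dict[str, tuple[bool, type | tuple]] = {
    "schema_version": (True, int),
    "command": (True, str),
    "seed": (True, int),
    "config_hash": (True, str),
    "versions": (True, dict),
    "N_grid": (False, list),
    "log_weights": (False, list),
    "probabilities": (False, list),
    "mode": (False, int),
    "mean": (False, _NUMBER),
    "node_posteriors": (False, list),
    "diagnostics": (False, dict),
    "boundary_flags": (False, dict),
    "labels": (False, list),
    "results": (False, dict),
}


class SchemaError(ValueError):
    pass


def validate_report(report: dict) -> None:
    """Structural validation of a report mapping against the shipped schema."""
    if not isinstance(report, dict):
        raise SchemaError("report must be a mapping")
    unknown = sorted(set(report) - set(REPORT_FIELDS))
    if unknown:
        raise SchemaError(f"unknown report fields: {', '.join(unknown)}")
    for name, (required, typ) in REPORT_FIELDS.items():
        if name not in report:
            if required:
                raise SchemaError(f"missing required report field {name!r}")
            continue
        if not isinstance(report[name], typ):
            raise SchemaError(f"report field {name!r} has the wrong type")
    if report["schema_version"] != REPORT_SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported schema version {report['schema_version']}"
        )
    probs = report.get("probabilities")
    if probs is not None:
        total = sum(probs)
        if abs(total - 1.0) > 1e-8:
            raise SchemaError(f"probabilities sum to {total}, not 1")
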