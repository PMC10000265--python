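"""Lossless JSON/YAML text forms for phenopacket documents.

The wire form follows the protobuf JSON mapping:

* field names are lowerCamelCase (``subjectOrBiosampleId``);
* unset optional fields, empty lists/maps, empty strings, ``false``
  booleans, zero numbers and default enum members are omitted;
* enum values are written as their wire names (UPPER_SNAKE, except the
  lowercase VRSATILE ``moleculeContext`` vocabulary);
* map keys are emitted sorted; output is deterministic — equal documents
  serialize to byte-identical text.

Reading is strict by default: an unknown key is an error naming its
document path. A lenient mode downgrades unknown keys to warnings and
preserves them on the document so they survive re-emission.

YAML is read with a loader whose implicit timestamp resolution is
disabled: ``created: 2021-05-14T10:35:00Z`` must stay a string, not
become a ``datetime``.
"""

from __future__ import annotations

import collections.abc as _abc
import dataclasses
import json
import typing
from enum import Enum
from typing import Any, Optional, Union

import yaml

from . import core_model as m
from .core_model import (
    Cohort,
    Family,
    InvariantError,
    Message,
    Phenopacket,
    Severity,
    ValidationIssue,
    field_hints,
)

__all__ = [
    "DocumentFormat",
    "HydrationError",
    "ParseError",
    "SerializationError",
    "UnknownFieldError",
    "convert",
    "from_jsonable",
    "read_document",
    "to_jsonable",
    "write_document",
]


class DocumentFormat(Enum):
    JSON = "json"
    YAML = "yaml"


_TOP_LEVEL = {"phenopacket": Phenopacket, "family": Family, "cohort": Cohort}


class SerializationError(ValueError):
    pass


class ParseError(SerializationError):
    """Malformed JSON/YAML, with line/column when the parser provides them."""

    def __init__(self, message: str, line: Optional[int] = None, column: Optional[int] = None) -> None:
        self.line = line
        self.column = column
        where = f" (line {line}, column {column})" if line is not None else ""
        super().__init__(f"{message}{where}")


class HydrationError(SerializationError):
    """A type or contract violation while building typed messages, located
    by document path."""

    def __init__(self, path: str, message: str) -> None:
        self.path = path or "/"
        self.message = message
        super().__init__(f"{self.path}: {message}")


class UnknownFieldError(HydrationError):
    pass


# --- naming ------------------------------------------------------------------


def _snake_to_camel(name: str) -> str:
    head, *rest = name.split("_")
    return head + "".join(part[:1].upper() + part[1:] for part in rest)


@typing.no_type_check
def _wire_names(cls: type) -> dict[str, str]:
    return _wire_names_cached(cls)


_WIRE_CACHE: dict[type, dict[str, str]] = {}


def _wire_names_cached(cls: type) -> dict[str, str]:
    cached = _WIRE_CACHE.get(cls)
    if cached is None:
        cached = {f.name: _snake_to_camel(f.name) for f in dataclasses.fields(cls)}
        _WIRE_CACHE[cls] = cached
    return cached


# --- emission ----------------------------------------------------------------


def _is_default(value: Any, hint: Any) -> bool:
    if value is None:
        return True
    if isinstance(value, Enum):
        return value is next(iter(type(value)))
    if isinstance(value, bool):
        return value is False
    if isinstance(value, (int, float)):
        return value == 0
    if isinstance(value, str):
        return value == ""
    if isinstance(value, (tuple, list, dict)):
        return len(value) == 0
    return False


def _emit_value(value: Any) -> Any:
    if isinstance(value, Message):
        return to_jsonable(value)
    if isinstance(value, Enum):
        return value.value
    if isinstance(value, (tuple, list)):
        return [_emit_value(v) for v in value]
    if isinstance(value, dict):
        return {k: value[k] for k in sorted(value)}
    if isinstance(value, float):
        if value == int(value) and abs(value) < 2**53:
            return int(value)
        return value
    return value


def to_jsonable(msg: Message) -> dict[str, Any]:
    """Render a message as plain dicts/lists ready for JSON or YAML."""
    cls = type(msg)
    out: dict[str, Any] = {}
    hints = field_hints(cls)
    for f in dataclasses.fields(msg):  # type: ignore[arg-type]
        value = getattr(msg, f.name)
        if _is_default(value, hints.get(f.name)):
            continue
        emitted = _emit_value(value)
        if emitted == {}:
            continue  # an all-default submessage is indistinguishable from unset
        out[_wire_names_cached(cls)[f.name]] = emitted
    unknown = getattr(msg, "_unknown", None)
    if unknown:
        for key in sorted(unknown):
            out.setdefault(key, unknown[key])
    return out


# --- hydration ---------------------------------------------------------------


def _unwrap(hint: Any) -> Any:
    """Strip Optional[...] down to the payload type."""
    origin = typing.get_origin(hint)
    if origin is typing.Union:
        args = [a for a in typing.get_args(hint) if a is not type(None)]
        if len(args) == 1:
            return args[0]
    return hint


def _hydrate_value(data: Any, hint: Any, path: str, strict: bool, warnings: Optional[list]) -> Any:
    hint = _unwrap(hint)
    origin = typing.get_origin(hint)
    if isinstance(hint, type) and issubclass(hint, Message):
        return from_jsonable(data, hint, path=path, strict=strict, warnings=warnings)
    if isinstance(hint, type) and issubclass(hint, Enum):
        if not isinstance(data, str):
            raise HydrationError(path, f"expected an enum name string, got {data!r}")
        for member in hint:
            if member.value == data:
                return member
        allowed = ", ".join(member.value for member in hint)
        raise HydrationError(path, f"unknown {hint.__name__} value {data!r}; allowed: {allowed}")
    if origin is tuple:
        if not isinstance(data, list):
            raise HydrationError(path, f"expected a list, got {type(data).__name__}")
        item_hint = typing.get_args(hint)[0]
        return tuple(
            _hydrate_value(item, item_hint, f"{path}/{i}", strict, warnings) for i, item in enumerate(data)
        )
    if origin in (dict, _abc.Mapping):
        if not isinstance(data, dict):
            raise HydrationError(path, f"expected a mapping, got {type(data).__name__}")
        for key, value in data.items():
            if not isinstance(key, str) or not isinstance(value, str):
                raise HydrationError(path, f"expected string-to-string mapping, got {key!r}: {value!r}")
        return dict(data)
    if hint is str:
        if not isinstance(data, str):
            raise HydrationError(path, f"expected a string, got {data!r}")
        return data
    if hint is bool:
        if not isinstance(data, bool):
            raise HydrationError(path, f"expected a boolean, got {data!r}")
        return data
    if hint is int:
        if isinstance(data, bool) or not isinstance(data, int):
            raise HydrationError(path, f"expected an integer, got {data!r}")
        return data
    if hint is float:
        if isinstance(data, bool) or not isinstance(data, (int, float)):
            raise HydrationError(path, f"expected a number, got {data!r}")
        return float(data)
    raise HydrationError(path, f"unsupported field type {hint!r}")  # pragma: no cover


def from_jsonable(
    data: Any,
    cls: type,
    *,
    path: str = "",
    strict: bool = True,
    warnings: Optional[list] = None,
) -> Any:
    """Build a typed message from plain dicts/lists.

    Unknown keys raise :class:`UnknownFieldError` when ``strict``;
    otherwise they are recorded as WARNING issues in ``warnings`` and
    preserved on the message for re-emission. Required fields (those
    without schema defaults) raise :class:`HydrationError` when absent.
    """
    if not isinstance(data, dict):
        raise HydrationError(path or "/", f"expected an object for {cls.__name__}, got {type(data).__name__}")
    hints = field_hints(cls)
    by_wire = {wire: name for name, wire in _wire_names_cached(cls).items()}
    kwargs: dict[str, Any] = {}
    unknown: dict[str, Any] = {}
    for key, value in data.items():
        field_name = by_wire.get(key)
        if field_name is None:
            key_path = f"{path}/{key}"
            if strict:
                raise UnknownFieldError(key_path, f"unknown field {key!r} for {cls.__name__}")
            unknown[key] = value
            if warnings is not None:
                warnings.append(
                    ValidationIssue(
                        severity=Severity.WARNING,
                        rule_id="unknown-field",
                        path=key_path,
                        message=f"unknown field {key!r} for {cls.__name__}; preserved verbatim",
                    )
                )
            continue
        kwargs[field_name] = _hydrate_value(value, hints[field_name], f"{path}/{key}", strict, warnings)
    for f in dataclasses.fields(cls):
        if (
            f.name not in kwargs
            and f.default is dataclasses.MISSING
            and f.default_factory is dataclasses.MISSING
        ):
            raise HydrationError(f"{path}/{_wire_names_cached(cls)[f.name]}", "required field is missing")
    try:
        msg = cls(**kwargs)
    except InvariantError as exc:
        raise HydrationError(f"{path}/{exc.path}" if exc.path else path, exc.message) from None
    if unknown:
        object.__setattr__(msg, "_unknown", unknown)
    return msg


# --- YAML dialect ------------------------------------------------------------


class _Loader(yaml.SafeLoader):
    """SafeLoader without implicit timestamp resolution (instants stay str)."""


_Loader.yaml_implicit_resolvers = {
    key: [(tag, regexp) for tag, regexp in resolvers if tag != "tag:yaml.org,2002:timestamp"]
    for key, resolvers in yaml.SafeLoader.yaml_implicit_resolvers.items()
}


class _Dumper(yaml.SafeDumper):
    def ignore_aliases(self, data: Any) -> bool:
        return True


_RESOLVER = yaml.resolver.Resolver()


def _represent_str(dumper: yaml.SafeDumper, data: str) -> yaml.Node:
    # Timestamp-shaped strings must be quoted so standard YAML loaders do
    # not resolve them into datetime objects.
    if _RESOLVER.resolve(yaml.ScalarNode, data, (True, False)) != "tag:yaml.org,2002:str":
        return dumper.represent_scalar("tag:yaml.org,2002:str", data, style="'")
    return dumper.represent_scalar("tag:yaml.org,2002:str", data)


_Dumper.add_representer(str, _represent_str)


# --- document-level API ------------------------------------------------------


def _resolve_top_level(top_level: Union[str, type]) -> type:
    if isinstance(top_level, str):
        try:
            return _TOP_LEVEL[top_level.lower()]
        except KeyError:
            raise SerializationError(
                f"unknown top-level document type {top_level!r}; expected one of {sorted(_TOP_LEVEL)}"
            ) from None
    return top_level


def _parse_text(text: str, fmt: DocumentFormat) -> Any:
    if fmt is DocumentFormat.JSON:
        try:
            return json.loads(text)
        except json.JSONDecodeError as exc:
            raise ParseError(exc.msg, exc.lineno, exc.colno) from None
    try:
        return yaml.load(text, Loader=_Loader)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        if mark is not None:
            raise ParseError(str(getattr(exc, "problem", exc)), mark.line + 1, mark.column + 1) from None
        raise ParseError(str(exc)) from None


def read_document(
    text: str,
    fmt: DocumentFormat = DocumentFormat.YAML,
    top_level: Union[str, type] = Phenopacket,
    *,
    strict: bool = True,
    warnings: Optional[list] = None,
) -> Any:
    """Parse JSON/YAML text into a fully-typed document.

    Input field order is irrelevant. ``warnings``, if given, receives
    unknown-field WARNING issues in lenient (``strict=False``) mode.
    """
    if not text or not text.strip():
        raise ParseError("empty document")
    cls = _resolve_top_level(top_level)
    data = _parse_text(text, fmt)
    return from_jsonable(data, cls, strict=strict, warnings=warnings)


def write_document(doc: Message, fmt: DocumentFormat = DocumentFormat.YAML) -> str:
    """Serialize a typed document to deterministic JSON or YAML text."""
    data = to_jsonable(doc)
    if fmt is DocumentFormat.JSON:
        return json.dumps(data, indent=2, ensure_ascii=False) + "\n"
    return yaml.dump(data, Dumper=_Dumper, sort_keys=False, allow_unicode=True, default_flow_style=False)


def convert(
    text: str,
    from_format: DocumentFormat,
    to_format: DocumentFormat,
    top_level: Union[str, type] = Phenopacket,
    *,
    strict: bool = True,
) -> str:
    """Re-serialize a document between JSON and YAML via the typed model."""
    return write_document(read_document(text, from_format, top_level, strict=strict), to_format)
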