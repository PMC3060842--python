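"""Relational-table introspection and data-access code generation.

Given a live connection to an embedded SQL database (sqlite3), this module
introspects a table into a :class:`TableDescriptor` — column names and
types, primary key, whether the key is auto-generated, and the presence of
the audit columns ``creationdate`` / ``modificationdate`` — and emits the
Python source of an accessor class wrapping the four persistence operations
persist (INSERT), update (UPDATE by key), retrieve (SELECT by key) and
delete (DELETE by key).  Caller code using the generated class contains no
SQL; every value is bound as a parameter, never interpolated.

Generated accessors:

* track a ``dirty`` flag (set by attribute assignment) and a ``persisted``
  flag;
* on persist, read back an auto-generated key and stamp both audit columns;
* on update, refresh ``modificationdate`` only, and no-op when not dirty;
* take an injectable ``clock`` callable (UTC timestamps from the client,
  not SQL NOW(), so behaviour is testable);
* are a pure function of the descriptor: the same descriptor always yields
  byte-identical source, headed by the tool version and a descriptor hash.

Because persist/update/retrieve/delete abstract away the table, hierarchies
of related records can be stored by composing persist calls (persist the
parent, feed its generated key to the children, persist those), with the
whole sequence inside one transaction when the connection is used that way.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import keyword
import re
import sqlite3
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional, Sequence

from .errors import CannotGenerateError, UnknownTableError, UnsupportedTypeError

TOOL_VERSION = "0.1.0"

AUDIT_COLUMNS = ("creationdate", "modificationdate")


class ColumnType(str, Enum):
    INTEGER = "integer"
    REAL = "real"
    TEXT = "text"
    BLOB = "blob"
    TIMESTAMP = "timestamp"


# declared-type token → mapped type; CLOB maps to unbounded text
_TYPE_MAP = {
    "INT": ColumnType.INTEGER,
    "INTEGER": ColumnType.INTEGER,
    "BIGINT": ColumnType.INTEGER,
    "SMALLINT": ColumnType.INTEGER,
    "REAL": ColumnType.REAL,
    "FLOAT": ColumnType.REAL,
    "DOUBLE": ColumnType.REAL,
    "NUMERIC": ColumnType.REAL,
    "DECIMAL": ColumnType.REAL,
    "TEXT": ColumnType.TEXT,
    "CLOB": ColumnType.TEXT,
    "VARCHAR": ColumnType.TEXT,
    "CHAR": ColumnType.TEXT,
    "BLOB": ColumnType.BLOB,
    "TIMESTAMP": ColumnType.TIMESTAMP,
    "DATETIME": ColumnType.TIMESTAMP,
}


@dataclass(frozen=True)
class Column:
    name: str
    type: ColumnType
    nullable: bool = True


@dataclass(frozen=True)
class TableDescriptor:
    """Introspected table metadata driving code generation."""

    table_name: str
    columns: tuple[Column, ...]
    primary_key: tuple[str, ...]
    pk_autogenerated: bool
    audit_columns: frozenset[str] = frozenset()

    def __post_init__(self):
        names = {c.name for c in self.columns}
        for pk in self.primary_key:
            if pk not in names:
                raise ValueError(f"primary key column {pk!r} not in columns")
        types = {c.name: c.type for c in self.columns}
        for a in self.audit_columns:
            if types.get(a) is not ColumnType.TIMESTAMP:
                raise ValueError(f"audit column {a!r} must be timestamp-typed")

    def content_hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:16]


def _map_type(declared: str, column: str) -> ColumnType:
    token = re.split(r"[(\s]", declared.strip().upper())[0]
    if token in _TYPE_MAP:
        return _TYPE_MAP[token]
    raise UnsupportedTypeError(
        f"column {column!r}: cannot map declared type {declared!r}"
    )


def introspect(connection: sqlite3.Connection, table_name: str) -> TableDescriptor:
    """Build a :class:`TableDescriptor` for an existing table.

    Audit columns are detected by exact lowercase name match against
    ``creationdate``/``modificationdate``.  ``pk_autogenerated`` is true for
    a single-column INTEGER PRIMARY KEY (the engine's rowid alias, which
    auto-generates keys on insert).
    """
    if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", table_name):
        raise UnknownTableError(f"invalid table name {table_name!r}")
    rows = connection.execute(f"PRAGMA table_info({table_name})").fetchall()
    if not rows:
        raise UnknownTableError(f"table {table_name!r} does not exist")
    columns = []
    pk_cols: list[tuple[int, str, str]] = []
    for _cid, name, declared, notnull, _default, pk in rows:
        ctype = _map_type(declared or "TEXT", name)
        columns.append(Column(name=name, type=ctype, nullable=not notnull))
        if pk:
            pk_cols.append((pk, name, declared or ""))
    pk_cols.sort()
    primary_key = tuple(name for _, name, _ in pk_cols)
    pk_auto = (
        len(pk_cols) == 1
        and _map_type(pk_cols[0][2] or "TEXT", pk_cols[0][1]) is ColumnType.INTEGER
    )
    audit = frozenset(
        c.name
        for c in columns
        if c.name in AUDIT_COLUMNS and c.type is ColumnType.TIMESTAMP
    )
    return TableDescriptor(
        table_name=table_name,
        columns=tuple(columns),
        primary_key=primary_key,
        pk_autogenerated=pk_auto,
        audit_columns=audit,
    )


def _class_name(table_name: str) -> str:
    name = "".join(p.capitalize() for p in re.split(r"[_\W]+", table_name) if p)
    return f"{name}Accessor"


def _attr(name: str) -> str:
    attr = re.sub(r"\W", "_", name)
    return attr + "_" if keyword.iskeyword(attr) else attr


def generate(descriptor: TableDescriptor, output_namespace: str = "generated") -> str:
    """Emit the Python source of a table accessor class.

    The emitted module imports cleanly on its own and exposes exactly the
    four persistence operations.  Raises :class:`CannotGenerateError` for a
    descriptor without a primary key or with a multi-column auto-generated
    key (the retrieval contract requires a usable key).
    """
    if not descriptor.primary_key:
        raise CannotGenerateError(
            f"table {descriptor.table_name!r} has no primary key; "
            "retrieve/update/delete require one"
        )
    if descriptor.pk_autogenerated and len(descriptor.primary_key) > 1:
        raise CannotGenerateError(
            f"table {descriptor.table_name!r}: multi-column auto-generated "
            "keys are not supported"
        )

    t = descriptor
    cls = _class_name(t.table_name)
    cols = [c.name for c in t.columns]
    attrs = {c: _attr(c) for c in cols}
    pk = list(t.primary_key)
    auto_pk = pk[0] if t.pk_autogenerated else None
    has_creation = "creationdate" in t.audit_columns
    has_modification = "modificationdate" in t.audit_columns

    # persist: caller-supplied columns = everything except an auto key;
    # audit columns are stamped by the library, not the caller
    insert_cols = [c for c in cols if c != auto_pk]
    update_cols = [
        c for c in cols if c not in pk and c != "creationdate"
    ]

    q = lambda c: f'"{c}"'  # noqa: E731 — common-denominator identifier quoting
    insert_sql = (
        f'INSERT INTO "{t.table_name}" ({", ".join(q(c) for c in insert_cols)}) '
        f'VALUES ({", ".join("?" * len(insert_cols))})'
    )
    where_pk = " AND ".join(f"{q(c)} = ?" for c in pk)
    update_sql = (
        f'UPDATE "{t.table_name}" SET {", ".join(f"{q(c)} = ?" for c in update_cols)} '
        f"WHERE {where_pk}"
    )
    select_sql = (
        f'SELECT {", ".join(q(c) for c in cols)} FROM "{t.table_name}" '
        f"WHERE {where_pk}"
    )
    delete_sql = f'DELETE FROM "{t.table_name}" WHERE {where_pk}'

    w: list[str] = []
    add = w.append
    add(f'"""Data accessor for table {t.table_name!r} (namespace {output_namespace}).')
    add("")
    add(f"Generated by proteokit dao-gen {TOOL_VERSION}; descriptor hash {t.content_hash()}.")
    add("Do not edit: regenerate from the table instead.")
    add('"""')
    add("")
    add("import datetime")
    add("")
    add("")
    add(f"class {cls}:")
    add(f'    """CRUD accessor for one row of {t.table_name!r}.')
    add("")
    add("    Attribute assignment marks the instance dirty; update() is a")
    add("    no-op on a clean instance. The clock callable supplies UTC")
    add("    timestamps for the audit columns.")
    add('    """')
    add("")
    add(f"    TABLE = {t.table_name!r}")
    add(f"    COLUMNS = {tuple(cols)!r}")
    add(f"    PRIMARY_KEY = {tuple(pk)!r}")
    add("")
    add("    def __init__(self, clock=None, **values):")
    add("        object.__setattr__(self, '_dirty', False)")
    add("        object.__setattr__(self, '_persisted', False)")
    add("        object.__setattr__(self, '_clock',")
    add("                           clock or (lambda: datetime.datetime.now(datetime.timezone.utc)))")
    for c in cols:
        add(f"        object.__setattr__(self, {attrs[c]!r}, values.get({attrs[c]!r}))")
    add("        object.__setattr__(self, '_dirty', False)")
    add("")
    add("    def __setattr__(self, name, value):")
    add("        object.__setattr__(self, name, value)")
    add("        if not name.startswith('_'):")
    add("            object.__setattr__(self, '_dirty', True)")
    add("")
    add("    @property")
    add("    def dirty(self):")
    add("        return self._dirty")
    add("")
    add("    @property")
    add("    def persisted(self):")
    add("        return self._persisted")
    add("")
    # ---- persist ----
    add("    def persist(self, connection):")
    add('        """INSERT this instance; stamps audit columns and reads back')
    add('        an auto-generated key. Returns self."""')
    stamp = []
    if has_creation:
        stamp.append("creationdate")
    if has_modification:
        stamp.append("modificationdate")
    if stamp:
        # timestamps stored as ISO-8601 text so they round-trip through the
        # engine unchanged and compare chronologically as strings
        add("        now = self._clock().isoformat(sep=' ')")
        for c in stamp:
            add(f"        object.__setattr__(self, {attrs[c]!r}, now)")
    add(f"        params = ({', '.join('self.' + attrs[c] for c in insert_cols)},)")
    add(f"        cursor = connection.execute({insert_sql!r}, params)")
    if auto_pk is not None:
        add(f"        if self.{attrs[auto_pk]} is None:")
        add(f"            object.__setattr__(self, {attrs[auto_pk]!r}, cursor.lastrowid)")
    add("        object.__setattr__(self, '_persisted', True)")
    add("        object.__setattr__(self, '_dirty', False)")
    add("        return self")
    add("")
    # ---- update ----
    add("    def update(self, connection):")
    add('        """UPDATE this row by primary key; refreshes modificationdate')
    add('        only. No-op (returns 0) when the instance is not dirty;')
    add('        otherwise returns the affected row count."""')
    add("        if not self._dirty:")
    add("            return 0")
    if not update_cols:
        # key-only table: nothing updatable
        add("        object.__setattr__(self, '_dirty', False)")
        add("        return 0")
    else:
        if has_modification:
            add("        object.__setattr__(self, 'modificationdate',")
            add("                           self._clock().isoformat(sep=' '))")
        add(f"        params = ({', '.join('self.' + attrs[c] for c in update_cols)},")
        add(f"                  {', '.join('self.' + attrs[c] for c in pk)},)")
        add(f"        cursor = connection.execute({update_sql!r}, params)")
        add("        object.__setattr__(self, '_dirty', False)")
        add("        return cursor.rowcount")
    add("")
    # ---- retrieve ----
    add("    @classmethod")
    add("    def retrieve(cls, connection, *key, clock=None):")
    add('        """SELECT one row by primary key; returns an instance or None."""')
    add(f"        row = connection.execute({select_sql!r}, key).fetchone()")
    add("        if row is None:")
    add("            return None")
    add("        instance = cls(clock=clock)")
    for i, c in enumerate(cols):
        add(f"        object.__setattr__(instance, {attrs[c]!r}, row[{i}])")
    add("        object.__setattr__(instance, '_persisted', True)")
    add("        object.__setattr__(instance, '_dirty', False)")
    add("        return instance")
    add("")
    # ---- delete ----
    add("    def delete(self, connection):")
    add('        """DELETE this row by primary key; returns the affected row')
    add('        count (0 when already absent)."""')
    add(f"        params = ({', '.join('self.' + attrs[c] for c in pk)},)")
    add(f"        cursor = connection.execute({delete_sql!r}, params)")
    add("        if cursor.rowcount:")
    add("            object.__setattr__(self, '_persisted', False)")
    add("        return cursor.rowcount")
    add("")
    return "\n".join(w)


def load_accessor(source: str):
    """Exec generated source in a fresh namespace; return the accessor class."""
    namespace: dict = {}
    exec(compile(source, "<generated accessor>", "exec"), namespace)
    classes = [
        v
        for v in namespace.values()
        if isinstance(v, type) and v.__name__.endswith("Accessor")
    ]
    return classes[0]


@dataclass
class CrudReport:
    """Outcome of :func:`crud_roundtrip`; ``ok`` with an empty failure list
    on success, otherwise the names of the failing checks."""

    ok: bool
    failures: list[str] = field(default_factory=list)


def crud_roundtrip(
    accessor_cls,
    connection: sqlite3.Connection,
    values: dict,
    mutate: dict,
    clock: Optional[Callable[[], _dt.datetime]] = None,
    transaction: bool = False,
) -> CrudReport:
    """Exercise persist → retrieve → update → retrieve → delete on a scratch
    table and verify every contract point.

    ``values`` seeds the row (audit and auto-key columns are stamped by the
    accessor); ``mutate`` maps column attributes to new values for the
    update step.  With ``transaction=True`` the whole cycle runs in a single
    explicit transaction.
    """
    failures: list[str] = []
    clocks = clock or _ticking_clock()
    obj = accessor_cls(clock=clocks, **values)
    pk_attrs = [a for a in accessor_cls.PRIMARY_KEY]

    if transaction:
        connection.execute("BEGIN")
    obj.persist(connection)
    if not obj.persisted:
        failures.append("persisted flag not set after persist")
    key = tuple(getattr(obj, a) for a in pk_attrs)
    if any(k is None for k in key):
        failures.append("primary key unset after persist")

    back = accessor_cls.retrieve(connection, *key, clock=clocks)
    if back is None:
        failures.append("retrieve after persist returned nothing")
    else:
        for col in accessor_cls.COLUMNS:
            a, b = getattr(obj, col), getattr(back, col)
            if a != b:
                failures.append(f"retrieve mismatch on {col!r}: {a!r} != {b!r}")

    creation_before = getattr(obj, "creationdate", None)
    modification_before = getattr(obj, "modificationdate", None)

    # no-op update on a clean instance
    if back is not None and back.update(connection) != 0:
        failures.append("update on clean instance was not a no-op")

    for attr, value in mutate.items():
        setattr(obj, attr, value)
    if mutate:
        if obj.update(connection) != 1:
            failures.append("dirty update did not affect exactly one row")
        after = accessor_cls.retrieve(connection, *key, clock=clocks)
        for attr, value in mutate.items():
            if getattr(after, attr) != value:
                failures.append(f"update not reflected for {attr!r}")
        if modification_before is not None:
            if not getattr(after, "modificationdate") > modification_before:
                failures.append("modificationdate not refreshed by update")
        if creation_before is not None:
            if getattr(after, "creationdate") != creation_before:
                failures.append("creationdate changed by update")

    if obj.delete(connection) != 1:
        failures.append("delete did not remove exactly one row")
    if accessor_cls.retrieve(connection, *key, clock=clocks) is not None:
        failures.append("row still present after delete")
    if obj.delete(connection) != 0:
        failures.append("second delete affected rows")
    if transaction:
        connection.commit()
    return CrudReport(ok=not failures, failures=failures)


def _ticking_clock(start: Optional[_dt.datetime] = None):
    """A deterministic UTC clock advancing one second per call."""
    state = {"t": start or _dt.datetime(2011, 3, 8, tzinfo=_dt.timezone.utc)}

    def clock() -> _dt.datetime:
        state["t"] += _dt.timedelta(seconds=1)
        return state["t"]

    return clock
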