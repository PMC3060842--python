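"""Table introspection, accessor generation and CRUD behaviour."""

import datetime
import random
import re
import sqlite3

import pytest

from proteokit.dao_codegen import (
    AUDIT_COLUMNS,
    ColumnType,
    TableDescriptor,
    Column,
    CrudReport,
    crud_roundtrip,
    generate,
    introspect,
    load_accessor,
)
from proteokit.errors import (
    CannotGenerateError,
    UnknownTableError,
    UnsupportedTypeError,
)
from proteokit.fixtures import FixtureSpec, make_schema

SPECTRUM_DDL = """
CREATE TABLE spectrum (
    id INTEGER PRIMARY KEY,
    title TEXT NOT NULL,
    data BLOB,
    creationdate TIMESTAMP,
    modificationdate TIMESTAMP
)
"""


@pytest.fixture
def connection():
    conn = sqlite3.connect(":memory:")
    yield conn
    conn.close()


@pytest.fixture
def spectrum_descriptor(connection):
    connection.execute(SPECTRUM_DDL)
    return introspect(connection, "spectrum")


class TestIntrospect:
    def test_detects_auto_key_and_audit_columns(self, spectrum_descriptor):
        d = spectrum_descriptor
        assert d.pk_autogenerated
        assert d.primary_key == ("id",)
        assert d.audit_columns == frozenset(AUDIT_COLUMNS)
        types = {c.name: c.type for c in d.columns}
        assert types["title"] is ColumnType.TEXT
        assert types["data"] is ColumnType.BLOB

    def test_composite_non_auto_key(self, connection):
        connection.execute(
            "CREATE TABLE link (a INTEGER, b INTEGER, note TEXT, PRIMARY KEY (a, b))"
        )
        d = introspect(connection, "link")
        assert not d.pk_autogenerated
        assert d.primary_key == ("a", "b")

    def test_missing_table_raises(self, connection):
        with pytest.raises(UnknownTableError):
            introspect(connection, "nope")

    def test_unmappable_type_names_the_column(self, connection):
        connection.execute("CREATE TABLE odd (id INTEGER PRIMARY KEY, g GEOMETRY)")
        with pytest.raises(UnsupportedTypeError, match="g"):
            introspect(connection, "odd")

    def test_clob_maps_to_text(self, connection):
        connection.execute("CREATE TABLE doc (id INTEGER PRIMARY KEY, body CLOB)")
        d = introspect(connection, "doc")
        assert {c.name: c.type for c in d.columns}["body"] is ColumnType.TEXT

    def test_audit_column_must_be_timestamp_typed(self):
        with pytest.raises(ValueError):
            TableDescriptor(
                table_name="t",
                columns=(Column("id", ColumnType.INTEGER), Column("creationdate", ColumnType.TEXT)),
                primary_key=("id",),
                pk_autogenerated=True,
                audit_columns=frozenset({"creationdate"}),
            )


class TestGenerate:
    def test_exactly_four_public_persistence_operations(self, spectrum_descriptor):
        source = generate(spectrum_descriptor)
        cls = load_accessor(source)
        public = [
            n
            for n in vars(cls)
            if not n.startswith("_")
            and callable(getattr(cls, n))
            and not isinstance(vars(cls)[n], (property, classmethod))
        ] + [n for n, v in vars(cls).items() if isinstance(v, classmethod)]
        assert sorted(public) == ["delete", "persist", "retrieve", "update"]

    def test_no_value_interpolation_in_sql(self, spectrum_descriptor):
        source = generate(spectrum_descriptor)
        for sql in re.findall(r"'(INSERT|UPDATE|SELECT|DELETE)[^']*'", source):
            assert "%" not in sql and "format(" not in sql
        # every statement is executed with a bound-parameter tuple
        assert "connection.execute" in source
        assert re.search(r"execute\('[^']+',\s*(params|key)\)", source)

    def test_generation_is_byte_deterministic(self, spectrum_descriptor):
        assert generate(spectrum_descriptor) == generate(spectrum_descriptor)

    def test_descriptor_without_pk_rejected(self):
        d = TableDescriptor(
            table_name="nokey",
            columns=(Column("x", ColumnType.TEXT),),
            primary_key=(),
            pk_autogenerated=False,
        )
        with pytest.raises(CannotGenerateError):
            generate(d)

    def test_provenance_header_carries_descriptor_hash(self, spectrum_descriptor):
        source = generate(spectrum_descriptor)
        assert spectrum_descriptor.content_hash() in source


class TestCrud:
    def _accessor(self, connection):
        connection.execute(SPECTRUM_DDL)
        return load_accessor(generate(introspect(connection, "spectrum")))

    def test_full_cycle_with_random_blob(self, connection):
        cls = self._accessor(connection)
        blob = random.Random(99).randbytes(1024)
        report = crud_roundtrip(
            cls,
            connection,
            values={"title": "scan 1", "data": blob},
            mutate={"title": "scan 1 (edited)"},
        )
        assert report == CrudReport(ok=True, failures=[])

    def test_persist_reads_back_autogenerated_key_and_stamps_audit(self, connection):
        cls = self._accessor(connection)
        obj = cls(title="s", data=b"\x00\x01")
        obj.persist(connection)
        assert obj.id is not None
        assert obj.persisted and not obj.dirty
        assert obj.creationdate == obj.modificationdate

    def test_update_refreshes_modificationdate_only(self, connection):
        cls = self._accessor(connection)
        obj = cls(title="s", data=b"")
        obj.persist(connection)
        created = obj.creationdate
        obj.title = "s2"
        assert obj.dirty
        assert obj.update(connection) == 1
        back = cls.retrieve(connection, obj.id)
        assert back.creationdate == created
        assert back.modificationdate > created

    def test_clean_update_is_a_noop(self, connection):
        cls = self._accessor(connection)
        obj = cls(title="s", data=b"").persist(connection)
        before = obj.modificationdate
        assert obj.update(connection) == 0
        assert cls.retrieve(connection, obj.id).modificationdate == before

    def test_delete_twice_reports_zero_rows_without_error(self, connection):
        cls = self._accessor(connection)
        obj = cls(title="s", data=b"").persist(connection)
        assert obj.delete(connection) == 1
        assert obj.delete(connection) == 0
        assert cls.retrieve(connection, obj.id) is None

    def test_transactional_cycle(self, connection):
        cls = self._accessor(connection)
        connection.isolation_level = None
        report = crud_roundtrip(
            cls,
            connection,
            values={"title": "tx", "data": b"x"},
            mutate={"title": "tx2"},
            transaction=True,
        )
        assert report.ok, report.failures

    def test_injectable_clock_drives_audit_values(self, connection):
        cls = self._accessor(connection)
        fixed = datetime.datetime(2011, 3, 8, 12, 0, tzinfo=datetime.timezone.utc)
        obj = cls(clock=lambda: fixed, title="s", data=b"")
        obj.persist(connection)
        assert obj.creationdate == fixed.isoformat(sep=" ")


class TestRandomSchemas:
    def test_generated_accessors_pass_crud_on_random_fixtures(self, connection):
        for sf in make_schema(FixtureSpec(seed=41, schema_count=10)):
            connection.execute(sf.create_sql)
            cls = load_accessor(generate(introspect(connection, sf.table_name)))
            report = crud_roundtrip(cls, connection, sf.values, sf.mutate)
            assert report.ok, (sf.table_name, report.failures)

    def test_parent_child_hierarchy_persists_through_the_same_interface(self, connection):
        connection.execute(
            "CREATE TABLE parent (id INTEGER PRIMARY KEY, name TEXT,"
            " creationdate TIMESTAMP, modificationdate TIMESTAMP)"
        )
        connection.execute(
            "CREATE TABLE child (id INTEGER PRIMARY KEY, parent_id INTEGER,"
            " payload BLOB)"
        )
        parent_cls = load_accessor(generate(introspect(connection, "parent")))
        child_cls = load_accessor(generate(introspect(connection, "child")))
        parent = parent_cls(name="root").persist(connection)
        child = child_cls(parent_id=parent.id, payload=b"leaf").persist(connection)
        row = connection.execute(
            "SELECT parent.name, child.payload FROM child"
            " JOIN parent ON parent.id = child.parent_id WHERE child.id = ?",
            (child.id,),
        ).fetchone()
        assert row == ("root", b"leaf")
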