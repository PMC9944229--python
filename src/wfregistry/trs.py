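"""Static GA4GH TRS (Tool Registry Service) response generation.

Published metadata documents are transformed into a path-addressed tree of
TRS 2.x response documents.  For each workflow version the tree holds the
main version document at ``/tools/{id}/versions/{version_id}`` and exactly
two sub-paths, ``.../files`` and ``.../tests``, plus the listing documents
``/tools``, ``/tools/{id}``, and ``/tools/{id}/versions``.  Writing the tree
as ``<path>/index.json`` files lets any static file server reproduce the
API byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

from .metadata import FileRole, WorkflowMetadata, serialize_metadata
from .resources import Resolver

__all__ = ["TrsDocumentTree", "to_trs", "write_registry", "FILE_TYPE_BY_ROLE"]

#: Mapping of metadata file roles to TRS file types.
FILE_TYPE_BY_ROLE = {
    FileRole.PRIMARY: "PRIMARY_DESCRIPTOR",
    FileRole.SECONDARY: "SECONDARY_DESCRIPTOR",
    FileRole.TEST: "TEST_FILE",
    FileRole.OTHER: "OTHER",
}

#: Name under which the source metadata document is co-published beside the
#: TRS version document (the registry's second per-version file).
METADATA_FILENAME = "workflow-metadata.json"


@dataclass
class TrsDocumentTree:
    """Path-addressed TRS response documents plus co-published metadata."""

    documents: dict[str, object] = field(default_factory=dict)
    #: (tool id, version) -> serialized source metadata text, published
    #: beside the version document.
    metadata_documents: dict[tuple[str, str], str] = field(default_factory=dict)

    def version_paths(self) -> list[str]:
        return [
            p
            for p in self.documents
            if "/versions/" in p and not p.endswith(("/files", "/tests"))
        ]


def _checksum(content: bytes, algorithm: str) -> dict:
    digest = hashlib.new(algorithm, content).hexdigest()
    return {"checksum": digest, "type": algorithm}


def to_trs(
    metas: list[WorkflowMetadata],
    registry_base_url: str,
    resolver: Resolver | None = None,
    verified: set[tuple[str, str]] | None = None,
    registry_name: str = "wfregistry",
    checksum_algorithm: str = "sha256",
) -> TrsDocumentTree:
    """Build the TRS document tree for a set of published metadata records.

    ``verified`` names the (id, version) pairs whose tests all passed; those
    versions carry ``verified: true`` with the registry name as
    ``verified_source``.  Checksums are computed through the resolver when
    one is given; file contents must be available at that point.
    """
    base = registry_base_url.rstrip("/")
    verified = verified or set()
    seen: set[tuple[str, str]] = set()
    by_id: dict[str, list[WorkflowMetadata]] = {}
    for meta in metas:
        key = (meta.id, meta.version)
        if key in seen:
            raise ValueError(f"duplicate workflow id/version pair: {key}")
        seen.add(key)
        by_id.setdefault(meta.id, []).append(meta)

    tree = TrsDocumentTree()
    tools_list = []
    for wid, versions in by_id.items():
        first = versions[0]
        version_docs = []
        for meta in versions:
            is_verified = (meta.id, meta.version) in verified
            vdoc = {
                "id": meta.version,
                "url": f"{base}/tools/{wid}/versions/{meta.version}",
                "name": meta.name,
                "author": [a.name or a.account for a in meta.authors],
                "descriptor_type": [meta.language.type.value],
                "verified": is_verified,
                "verified_source": [registry_name] if is_verified else [],
                "meta_version": meta.version,
            }
            version_docs.append(vdoc)

            files_doc = []
            for f in meta.files:
                entry = {
                    "path": f.target,
                    "file_type": FILE_TYPE_BY_ROLE[f.role],
                }
                if resolver is not None:
                    got = resolver.resolve(f.url)
                    if got.exists:
                        entry["checksum"] = _checksum(got.content, checksum_algorithm)
                files_doc.append(entry)

            tests_doc = []
            for t in meta.testing:
                params_text = None
                if resolver is not None and t.params_file is not None:
                    got = resolver.resolve(t.params_file.url)
                    if got.exists:
                        params_text = got.text
                tests_doc.append({"id": t.test_id, "test": params_text})

            vpath = f"/tools/{wid}/versions/{meta.version}"
            tree.documents[vpath] = vdoc
            tree.documents[f"{vpath}/files"] = files_doc
            tree.documents[f"{vpath}/tests"] = tests_doc
            tree.metadata_documents[(wid, meta.version)] = serialize_metadata(
                meta, "json"
            )

        tool_doc = {
            "id": wid,
            "url": f"{base}/tools/{wid}",
            "name": first.name,
            "organization": first.authors[0].account if first.authors else "",
            "toolclass": {"id": "1", "name": "Workflow", "description": "A computational workflow"},
            "versions": version_docs,
        }
        tree.documents[f"/tools/{wid}"] = tool_doc
        tree.documents[f"/tools/{wid}/versions"] = version_docs
        tools_list.append(tool_doc)

    tree.documents["/tools"] = tools_list
    return tree


def _dump(doc: object) -> str:
    return json.dumps(doc, indent=2, ensure_ascii=False, sort_keys=False) + "\n"


def write_registry(tree: TrsDocumentTree, out_dir: str | os.PathLike) -> list[str]:
    """Write every endpoint path as ``<out_dir>/<path>/index.json``.

    The source metadata document is co-published beside each version
    document.  Serialization is deterministic: writing the same tree twice
    yields byte-identical output.
    """
    out_dir = os.fspath(out_dir)
    written: list[str] = []
    for path in sorted(tree.documents):
        doc_dir = os.path.join(out_dir, path.lstrip("/"))
        os.makedirs(doc_dir, exist_ok=True)
        target = os.path.join(doc_dir, "index.json")
        with open(target, "w", encoding="utf-8") as fh:
            fh.write(_dump(tree.documents[path]))
        written.append(target)
    for (wid, version), text in sorted(tree.metadata_documents.items()):
        doc_dir = os.path.join(out_dir, "tools", wid, "versions", version)
        os.makedirs(doc_dir, exist_ok=True)
        target = os.path.join(doc_dir, METADATA_FILENAME)
        with open(target, "w", encoding="utf-8") as fh:
            fh.write(text)
        written.append(target)
    return written
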