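"""Picture registration, plot/accession linking and search.

Images document plots and accessions non-destructively; they are referenced
by locator (file path or URL), never copied into the store. Embedded camera
metadata (make, model, exposure time, timestamp) is extracted from local
files when readable; extraction failures degrade to null fields, never to
errors. Pictures relate n:m to plots and to accessions through link tables,
the only place deletes cascade.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional, Union

import pandas as pd
from PIL import ExifTags, Image

from .core import InvariantError, Picture, PictureFile
from .store import PhenoStore, StoreIntegrityError, _EXP_COLS

__all__ = ["register_picture", "link_picture", "unlink_picture", "search_pictures"]

_URL = re.compile(r"^[a-z][a-z0-9+.-]*://", re.IGNORECASE)

_EXIF_FIELDS = {
    "Make": "camera_make",
    "Model": "camera_model",
    "ExposureTime": "exposure",
    "DateTimeOriginal": "taken_at",
    "DateTime": "taken_at",
}


def _extract_exif(path: Path) -> dict:
    meta: dict = {}
    try:
        with Image.open(path) as im:
            exif = im.getexif()
            tags = {ExifTags.TAGS.get(k, k): v for k, v in exif.items()}
            ifd = exif.get_ifd(ExifTags.IFD.Exif)
            tags.update({ExifTags.TAGS.get(k, k): v for k, v in ifd.items()})
        for tag, fieldname in _EXIF_FIELDS.items():
            if tag in tags and fieldname not in meta:
                meta[fieldname] = str(tags[tag])
    except Exception:
        return {}  # unreadable metadata is a warning case, not an error
    return meta


def register_picture(
    store: PhenoStore,
    locator: Union[str, Path],
    metadata: Optional[dict] = None,
    description: Optional[str] = None,
    picture_id: Optional[str] = None,
) -> tuple[Picture, PictureFile]:
    """Register an image by path or URL.

    Local files must exist; their embedded metadata is read when possible.
    URL locators are stored verbatim with no extraction. A locator may be
    registered only once.
    """
    loc = str(locator)
    is_url = bool(_URL.match(loc))
    meta: dict = {}
    size = None
    if not is_url:
        p = Path(loc)
        if not p.is_file():
            raise FileNotFoundError(f"no such image file: {loc}")
        meta = _extract_exif(p)
        size = p.stat().st_size
    if metadata:
        meta.update(metadata)
    pid = picture_id or f"pic-{abs(hash(loc)) % 10**10:010d}"
    suffix = Path(loc.split("?")[0]).suffix.lstrip(".").lower() or "unknown"
    picture = Picture(
        picture_id=pid,
        description=description,
        camera_make=meta.get("camera_make"),
        camera_model=meta.get("camera_model"),
        exposure=meta.get("exposure"),
        taken_at=meta.get("taken_at"),
    )
    pfile = PictureFile(picture_id=pid, locator=loc, file_type=suffix, size_bytes=size)
    store.upsert(picture)
    try:
        store.upsert(pfile)
    except StoreIntegrityError as e:
        raise StoreIntegrityError(f"locator already registered: {loc}") from e
    return picture, pfile


def link_picture(
    store: PhenoStore,
    picture_id: str,
    plot_key: Optional[tuple] = None,
    accession_key: Optional[tuple] = None,
) -> int:
    """Link a picture to a plot and/or an accession (n:m, idempotent).

    Returns the number of new link rows (0 when both links already exist).
    """
    if plot_key is None and accession_key is None:
        raise InvariantError("link_picture needs a plot and/or an accession")
    conn = store._conn
    created = 0
    with conn:
        if plot_key is not None:
            cols = ("picture_id",) + _EXP_COLS + ("lane", "plot")
            vals = (picture_id,) + tuple(map(str, plot_key[:4])) + tuple(plot_key[4:])
            try:
                cur = conn.execute(
                    f"INSERT OR IGNORE INTO plot_picture ({', '.join(cols)})"
                    f" VALUES ({', '.join('?' for _ in cols)})",
                    vals,
                )
                created += cur.rowcount
            except Exception as e:
                raise StoreIntegrityError(str(e)) from e
        if accession_key is not None:
            try:
                cur = conn.execute(
                    "INSERT OR IGNORE INTO accession_picture"
                    " (picture_id, holding_institute_code, accession_number) VALUES (?, ?, ?)",
                    (picture_id,) + tuple(accession_key),
                )
                created += cur.rowcount
            except Exception as e:
                raise StoreIntegrityError(str(e)) from e
    return created


def unlink_picture(
    store: PhenoStore,
    picture_id: str,
    plot_key: Optional[tuple] = None,
    accession_key: Optional[tuple] = None,
) -> int:
    """Remove link rows; the picture and its file rows are never deleted."""
    conn = store._conn
    removed = 0
    with conn:
        if plot_key is not None:
            where = " AND ".join(f"{c} = ?" for c in _EXP_COLS + ("lane", "plot"))
            cur = conn.execute(
                f"DELETE FROM plot_picture WHERE picture_id = ? AND {where}",
                (picture_id,) + tuple(map(str, plot_key[:4])) + tuple(plot_key[4:]),
            )
            removed += cur.rowcount
        if accession_key is not None:
            cur = conn.execute(
                "DELETE FROM accession_picture WHERE picture_id = ?"
                " AND holding_institute_code = ? AND accession_number = ?",
                (picture_id,) + tuple(accession_key),
            )
            removed += cur.rowcount
    return removed


def search_pictures(
    store: PhenoStore,
    genus: Optional[str] = None,
    species: Optional[str] = None,
    experiment_key: Optional[tuple] = None,
) -> pd.DataFrame:
    """Search pictures by taxonomy and/or experiment.

    Taxonomy matches accessions linked directly or via a linked plot;
    the experiment filter matches pictures linked to that experiment's
    plots. Multiple criteria intersect. Each result row carries its linking
    context (accession identity or plot coordinates).
    """
    if genus is None and species is None and experiment_key is None:
        raise InvariantError("search needs at least one criterion")
    conn = store._conn

    def _ids(sql, params):
        return {r["picture_id"] for r in conn.execute(sql, params)}

    candidate = None
    if genus is not None or species is not None:
        conds, params = [], []
        if genus is not None:
            conds.append("a.genus = ?")
            params.append(genus)
        if species is not None:
            conds.append("a.species = ?")
            params.append(species)
        where = " AND ".join(conds)
        via_acc = _ids(
            "SELECT ap.picture_id FROM accession_picture ap JOIN accession a"
            " ON ap.holding_institute_code = a.holding_institute_code"
            " AND ap.accession_number = a.accession_number WHERE " + where,
            params,
        )
        via_plot = _ids(
            "SELECT pp.picture_id FROM plot_picture pp"
            " JOIN plot p ON "
            + " AND ".join(f"pp.{c} = p.{c}" for c in _EXP_COLS + ("lane", "plot"))
            + " JOIN accession a ON p.holding_institute_code = a.holding_institute_code"
            " AND p.accession_number = a.accession_number WHERE " + where,
            params,
        )
        candidate = via_acc | via_plot
    if experiment_key is not None:
        where = " AND ".join(f"{c} = ?" for c in _EXP_COLS)
        via_exp = _ids(
            f"SELECT picture_id FROM plot_picture WHERE {where}",
            tuple(map(str, experiment_key)),
        )
        candidate = via_exp if candidate is None else candidate & via_exp

    if not candidate:
        return pd.DataFrame(
            columns=["picture_id", "locator", "description", "context_kind", "context"]
        )
    marks = ", ".join("?" for _ in candidate)
    ids = tuple(sorted(candidate))
    rows = []
    for r in conn.execute(
        f"""SELECT pic.picture_id, pf.locator, pic.description
            FROM picture pic LEFT JOIN picture_file pf ON pic.picture_id = pf.picture_id
            WHERE pic.picture_id IN ({marks})""",
        ids,
    ):
        base = dict(r)
        for link in conn.execute(
            f"SELECT * FROM accession_picture WHERE picture_id = ?", (r["picture_id"],)
        ):
            rows.append(
                base
                | {
                    "context_kind": "accession",
                    "context": f"{link['holding_institute_code']}:{link['accession_number']}",
                }
            )
        for link in conn.execute(
            f"SELECT * FROM plot_picture WHERE picture_id = ?", (r["picture_id"],)
        ):
            rows.append(
                base
                | {
                    "context_kind": "plot",
                    "context": "/".join(str(link[c]) for c in _EXP_COLS)
                    + f" lane {link['lane']} plot {link['plot']}",
                }
            )
    return pd.DataFrame(rows)
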