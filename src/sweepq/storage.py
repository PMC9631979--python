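"""Uniform file-transfer abstraction over storage backends.

Pipelines push simulation outputs to (and pull inputs from) a shared
location through one small contract: connect, upload, download, delete,
rename, plus recursive folder counterparts.  The reference backend is a
sandboxed local folder, which makes the whole suite runnable offline;
cloud-service adapters (Box-style or Drive-style APIs, which require
per-user credentials) implement the same contract.
"""

from __future__ import annotations

import abc
import logging
import os
import shutil
from pathlib import Path, PurePosixPath

from .errors import ConflictError, NotFoundError, StorageError

log = logging.getLogger(__name__)


class Storage(abc.ABC):
    """Adapter contract for storage services.

    Remote locations are slash-separated paths relative to the storage
    root.  All transfer methods require :meth:`connect` to have been
    called; transfers are byte-faithful.
    """

    def __init__(self) -> None:
        self.connected = False

    @abc.abstractmethod
    def connect(self) -> "Storage":
        """Establish the connection; idempotent.  Returns self."""

    @abc.abstractmethod
    def upload_file(self, local_path, remote_path) -> bool: ...

    @abc.abstractmethod
    def download_file(self, remote_path, local_path) -> bool: ...

    @abc.abstractmethod
    def delete_file(self, remote_path) -> bool: ...

    @abc.abstractmethod
    def rename_file(self, remote_path, new_name) -> bool: ...

    def upload_folder(self, local_dir, remote_dir) -> bool:
        """Recursively upload a directory tree."""
        local_dir = Path(local_dir)
        if not local_dir.is_dir():
            raise NotFoundError(f"local folder {local_dir} does not exist")
        for path in sorted(local_dir.rglob("*")):
            if path.is_file():
                rel = path.relative_to(local_dir).as_posix()
                self.upload_file(path, f"{remote_dir}/{rel}")
        return True

    def download_folder(self, remote_dir, local_dir) -> bool:
        """Recursively download a directory tree."""
        names = self.list_files(remote_dir)
        if not names:
            raise NotFoundError(f"remote folder {remote_dir!r} is empty or absent")
        for rel in names:
            self.download_file(f"{remote_dir}/{rel}", Path(local_dir) / rel)
        return True

    @abc.abstractmethod
    def list_files(self, remote_dir) -> list[str]:
        """Relative paths of all files under a remote directory."""

    def _require_connected(self) -> None:
        if not self.connected:
            raise StorageError("storage not connected; call connect() first")


class LocalFolderStorage(Storage):
    """Storage rooted at a local directory; the offline reference backend.

    Remote paths are confined to the root: parent-directory escapes raise
    an error instead of touching files outside the sandbox.
    """

    def __init__(self, root: str | os.PathLike) -> None:
        super().__init__()
        self.root = Path(root)

    def connect(self) -> "LocalFolderStorage":
        try:
            self.root.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise StorageError(f"cannot create storage root {self.root}: {exc}") from exc
        self.connected = True
        return self

    def _resolve(self, remote_path) -> Path:
        parts = PurePosixPath(str(remote_path)).parts
        if any(part in ("..", "/") for part in parts) or str(remote_path).startswith("/"):
            raise StorageError(f"remote path {remote_path!r} escapes the storage root")
        return self.root.joinpath(*parts)

    def upload_file(self, local_path, remote_path) -> bool:
        self._require_connected()
        local_path = Path(local_path)
        if not local_path.is_file():
            raise NotFoundError(f"local file {local_path} does not exist")
        target = self._resolve(remote_path)
        if target.exists():
            log.info("overwriting %s", remote_path)
        target.parent.mkdir(parents=True, exist_ok=True)
        shutil.copyfile(local_path, target)
        return True

    def download_file(self, remote_path, local_path) -> bool:
        self._require_connected()
        source = self._resolve(remote_path)
        if not source.is_file():
            raise NotFoundError(f"remote file {remote_path!r} does not exist")
        local_path = Path(local_path)
        local_path.parent.mkdir(parents=True, exist_ok=True)
        shutil.copyfile(source, local_path)
        return True

    def delete_file(self, remote_path) -> bool:
        self._require_connected()
        target = self._resolve(remote_path)
        if not target.is_file():
            raise NotFoundError(f"remote file {remote_path!r} does not exist")
        target.unlink()
        return True

    def rename_file(self, remote_path, new_name: str) -> bool:
        self._require_connected()
        source = self._resolve(remote_path)
        if not source.is_file():
            raise NotFoundError(f"remote file {remote_path!r} does not exist")
        target = source.with_name(new_name)
        if target.exists():
            raise ConflictError(f"rename target {new_name!r} already exists")
        source.rename(target)
        return True

    def list_files(self, remote_dir) -> list[str]:
        self._require_connected()
        base = self._resolve(remote_dir)
        if not base.is_dir():
            return []
        return sorted(
            p.relative_to(base).as_posix() for p in base.rglob("*") if p.is_file()
        )
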