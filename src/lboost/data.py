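"""The universal input container: a binary predictor matrix with a binary response."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BinaryDataset"]


@dataclass
class BinaryDataset:
    """An n x p matrix of 0/1 predictors plus a 0/1 response vector.

    Predictors are typically dominant or recessive genotype indicators for
    SNPs; the response is disease status (1 = case).
    """

    X: np.ndarray
    y: np.ndarray
    columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.uint8)
        self.y = np.asarray(self.y, dtype=np.uint8)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must match number of rows of X")
        for name, arr in (("X", self.X), ("y", self.y)):
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{name} must contain only 0/1 values")
        if not self.columns:
            self.columns = [f"X{j + 1}" for j in range(self.X.shape[1])]
        elif len(self.columns) != self.X.shape[1]:
            raise ValueError("column names do not match number of predictors")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str = "y") -> "BinaryDataset":
        if response not in df.columns:
            raise ValueError(f"response column {response!r} not found")
        y = df[response].to_numpy()
        Xdf = df.drop(columns=[response])
        return cls(Xdf.to_numpy(), y, columns=list(Xdf.columns))

    def to_dataframe(self, response: str = "y") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.columns)
        df.insert(0, response, self.y)
        return df

    @classmethod
    def read_csv(cls, path, response: str = "y", **kwargs) -> "BinaryDataset":
        return cls.from_dataframe(pd.read_csv(path, **kwargs), response=response)

    def to_csv(self, path, response: str = "y") -> None:
        self.to_dataframe(response=response).to_csv(path, index=False)
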