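"""The two-action Connect-4 application and the random-play baseline.

The board is the standard 6 rows x 7 columns.  A BCI user needs only two
actions: ``select_next_column`` advances a highlighted cursor (wrapping
from the rightmost column back to the leftmost) and ``place_coin`` drops a
coin into the cursor column.  The computer opponent is a simple heuristic:
play an immediately winning column if one exists, otherwise block an
opponent's immediate win, otherwise pick a uniformly random legal column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = [
    "ROWS",
    "COLS",
    "Action",
    "GameState",
    "apply_action",
    "winner_check",
    "legal_columns",
    "drop_coin",
    "random_move",
    "heuristic_move",
    "simulate_matches",
]

log = logging.getLogger(__name__)

ROWS, COLS = 6, 7


class Action(Enum):
    SELECT_NEXT_COLUMN = "select_next_column"
    PLACE_COIN = "place_coin"


@dataclass
class GameState:
    """Immutable-by-convention game snapshot; cells are 0/1/2."""

    board: np.ndarray = field(
        default_factory=lambda: np.zeros((ROWS, COLS), dtype=np.int8)
    )
    to_move: int = 1
    cursor: int = 0
    status: str = "ongoing"  # ongoing | win1 | win2 | draw

    def __post_init__(self) -> None:
        self.board = np.asarray(self.board, dtype=np.int8)
        if self.board.shape != (ROWS, COLS):
            raise ValueError(f"board must be {ROWS}x{COLS}")
        # gravity: no empty cell below an occupied one
        occ = self.board != 0
        if np.any(occ[:-1] & ~occ[1:]):
            raise ValueError("gravity violated: floating coin")
        counts = np.bincount(self.board.ravel(), minlength=3)
        if counts[1] - counts[2] not in (0, 1):
            raise ValueError("piece-count difference must be 0 or 1")
        if not 0 <= self.cursor < COLS:
            raise ValueError("cursor out of range")

    def render(self) -> str:
        """Six-line text grid ('.', 'X' player 1, 'O' player 2)."""
        chars = {0: ".", 1: "X", 2: "O"}
        return "\n".join(
            "".join(chars[int(c)] for c in row) for row in self.board
        )


def legal_columns(board: np.ndarray) -> list[int]:
    return [c for c in range(COLS) if board[0, c] == 0]


def drop_coin(board: np.ndarray, col: int, player: int) -> np.ndarray:
    """Return a new board with *player*'s coin in the lowest empty cell."""
    if board[0, col] != 0:
        raise ValueError(f"column {col} is full")
    out = board.copy()
    row = int(np.max(np.nonzero(out[:, col] == 0)[0]))
    out[row, col] = player
    return out


def _drop_row(board: np.ndarray, col: int) -> int:
    return int(np.max(np.nonzero(board[:, col] == 0)[0]))


def _drop_wins(board: np.ndarray, col: int, player: int) -> bool:
    """Would dropping *player*'s coin in *col* complete four-in-line?

    Only lines through the landing cell can change, so a local run-length
    count is equivalent to a full-board scan after the drop.
    """
    r = _drop_row(board, col)
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        run = 1
        for sgn in (1, -1):
            rr, cc = r + sgn * dr, col + sgn * dc
            while 0 <= rr < ROWS and 0 <= cc < COLS and board[rr, cc] == player:
                run += 1
                rr += sgn * dr
                cc += sgn * dc
        if run >= 4:
            return True
    return False


def winner_check(board: np.ndarray) -> str:
    """Scan all 4-in-line windows (69 on 6x7); draw iff full and no win."""
    for player in (1, 2):
        m = board == player
        horiz = m[:, :-3] & m[:, 1:-2] & m[:, 2:-1] & m[:, 3:]
        vert = m[:-3] & m[1:-2] & m[2:-1] & m[3:]
        diag1 = m[:-3, :-3] & m[1:-2, 1:-2] & m[2:-1, 2:-1] & m[3:, 3:]
        diag2 = m[:-3, 3:] & m[1:-2, 2:-1] & m[2:-1, 1:-2] & m[3:, :-3]
        if horiz.any() or vert.any() or diag1.any() or diag2.any():
            return f"win{player}"
    if not legal_columns(board):
        return "draw"
    return "ongoing"


def apply_action(s: GameState, a: Action) -> GameState:
    """One BCI action; returns a new state.

    Placing a coin on a full column is a no-op (logged): the user must
    re-select, keeping control errors visible rather than silently fixed.
    """
    if s.status != "ongoing":
        raise ValueError(f"game over ({s.status}); no further actions")
    if a is Action.SELECT_NEXT_COLUMN:
        return replace(s, cursor=(s.cursor + 1) % COLS)
    if s.board[0, s.cursor] != 0:
        log.warning("place_coin rejected: column %d is full", s.cursor)
        return s
    board = drop_coin(s.board, s.cursor, s.to_move)
    return GameState(
        board=board,
        to_move=3 - s.to_move,
        cursor=s.cursor,
        status=winner_check(board),
    )


# ---------------------------------------------------------------------------
# Move policies and the random-play baseline simulation
# ---------------------------------------------------------------------------

def random_move(board: np.ndarray, player: int, rng: np.random.Generator) -> int:
    """Uniformly random legal column."""
    return int(rng.choice(legal_columns(board)))


def heuristic_move(board: np.ndarray, player: int, rng: np.random.Generator) -> int:
    """Win in one if possible, else block, else uniform random.

    With several blocking options only the lowest-index threat is blocked
    (a double threat cannot be parried anyway) -- this is what lets a
    random opponent win at all.
    """
    cols = legal_columns(board)
    if not cols:
        raise ValueError("no legal move on a full board")
    opponent = 3 - player
    for c in cols:
        if _drop_wins(board, c, player):
            return c
    for c in cols:
        if _drop_wins(board, c, opponent):
            return c
    return int(rng.choice(cols))


_POLICIES = {"random": random_move, "heuristic": heuristic_move}


def simulate_matches(
    n: int,
    player_a="random",
    player_b="heuristic",
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """Simulate *n* games, alternating who moves first.

    Policies are names ("random"/"heuristic") or callables
    ``(board, player, rng) -> column``.  Returns win/draw percentages
    summing to exactly 100.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pol_a = _POLICIES.get(player_a, player_a)
    pol_b = _POLICIES.get(player_b, player_b)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    counts = {"winA": 0, "winB": 0, "draw": 0}
    for game in range(n):
        # player A is board-player 1; alternate who moves first
        board = np.zeros((ROWS, COLS), dtype=np.int8)
        player = 1 if game % 2 == 0 else 2
        status = "ongoing"
        while status == "ongoing":
            policy = pol_a if player == 1 else pol_b
            col = policy(board, player, rng)
            won = _drop_wins(board, col, player)
            board = drop_coin(board, col, player)
            if won:
                status = f"win{player}"
            elif not legal_columns(board):
                status = "draw"
            player = 3 - player
        if status == "win1":
            counts["winA"] += 1
        elif status == "win2":
            counts["winB"] += 1
        else:
            counts["draw"] += 1
    return {k: 100.0 * v / n for k, v in counts.items()}
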