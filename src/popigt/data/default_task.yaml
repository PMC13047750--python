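# Default Play-or-Pass IGT configuration: 120 trials, 30 presentations
# per deck, $2000 starting bank. Presentation order generated once
# (build seed 20240) and frozen; outcome sequences fixed per deck.
n_trials: 120
presentations_per_deck: 30
starting_bank: 2000.0
timeout_seconds: 4.0
presentation_order: [A, C, B, D, C, D, B, A, B, D, C, A, B, C, A, D, C, B, A, D, D,
  B, C, A, A, D, C, B, B, A, C, D, B, C, D, A, A, C, D, B, A, D, B, C, D, A, B, C,
  C, B, D, A, A, D, B, C, A, B, C, D, A, D, C, B, C, D, B, A, C, D, A, B, B, D, A,
  C, B, C, D, A, B, A, C, D, B, A, C, D, D, C, A, B, A, C, B, D, D, B, C, A, A, D,
  C, B, B, D, C, A, A, C, D, B, B, D, C, A, C, A, B, D]
schedules:
  A:
    win_amount: 100.0
    loss_pattern: [-150.0, -200.0, -250.0, -300.0, -350.0]
    block_length: 10
    loss_positions: [2, 4, 5, 7, 9]
  B:
    win_amount: 100.0
    loss_pattern: [-1250.0]
    block_length: 10
    loss_positions: [8]
  C:
    win_amount: 50.0
    loss_pattern: [-50.0, -50.0, -50.0, -50.0, -50.0]
    block_length: 10
    loss_positions: [1, 3, 6, 7, 9]
  D:
    win_amount: 50.0
    loss_pattern: [-250.0]
    block_length: 10
    loss_positions: [9]
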