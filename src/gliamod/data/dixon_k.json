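{
"OX": -0.5,
"OXO": 0.842,
"OXOO": 0.299,
"OXOOO": -0.157,
"OXOOOO": -0.547,
"OXOOOX": -1.25,
"OXOOX": -0.878,
"OXOOXO": 0.372,
"OXOOXX": -0.169,
"OXOX": -0.5,
"OXOXO": 0.701,
"OXOXOO": 0.022,
"OXOXOX": -0.5,
"OXOXX": 0.084,
"OXOXXO": 1.169,
"OXOXXX": 0.611,
"OXX": -0.178,
"OXXO": 1.0,
"OXXOO": 0.305,
"OXXOOO": -0.296,
"OXXOOX": -0.831,
"OXXOX": -0.305,
"OXXOXO": 0.831,
"OXXOXX": 0.296,
"OXXX": 0.194,
"OXXXO": 1.288,
"OXXXOO": 0.5,
"OXXXOX": -0.043,
"OXXXX": 0.555,
"OXXXXO": 1.603,
"OXXXXX": 0.893,
"XO": 0.5,
"XOO": 0.178,
"XOOO": -0.194,
"XOOOO": -0.555,
"XOOOOO": -0.893,
"XOOOOX": -1.603,
"XOOOX": -1.288,
"XOOOXO": 0.043,
"XOOOXX": -0.5,
"XOOX": -1.0,
"XOOXO": 0.305,
"XOOXOO": -0.296,
"XOOXOX": -0.831,
"XOOXX": -0.305,
"XOOXXO": 0.831,
"XOOXXX": 0.296,
"XOX": -0.842,
"XOXO": 0.5,
"XOXOO": -0.084,
"XOXOOO": -0.611,
"XOXOOX": -1.169,
"XOXOX": -0.701,
"XOXOXO": 0.5,
"XOXOXX": -0.022,
"XOXX": -0.299,
"XOXXO": 0.878,
"XOXXOO": 0.169,
"XOXXOX": -0.372,
"XOXXX": 0.157,
"XOXXXO": 1.25,
"XOXXXX": 0.547
}
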