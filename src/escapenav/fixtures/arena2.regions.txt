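..................................................
..................................................
..................................................
..................................................
..................................................
..................................................
.......................SSS........................
.......................SSS........................
.......................SSS........................
...........LLLLLLLLLLLL...R.......................
..........L................R......................
..........L.................R.....................
..........L..................R....................
..........L..................R....................
..........L..................R....................
..........L..................R....................
..........L..................R....................
..........L..................R....................
..........L..................R....................
..........L..................R....................
..........L..................R....................
..........L..................R....................
..........L..................R....................
..........L..................R....................
..........L..................R....................
..........L..................R....................
..........L..................R....................
..........L..................R....................
..........L..................R....................
..........L..................R....................
..........L..................R....................
..........L..................R....................
..........L..................R....................
..........L..................R....................
..........L..................R....................
..........L..................R....................
..........LLLLLLLLL..........R....................
...................L.........R....................
....................L.......R.....................
.....................L.....R......................
......................L...R.......................
.......................TTT........................
.......................TTT........................
.......................TTT........................
..................................................
..................................................
..................................................
..................................................
..................................................
..................................................
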