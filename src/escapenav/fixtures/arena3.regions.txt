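..................................................
..................................................
..................................................
..................................................
..................................................
..................................................
.......................SSS........................
.......................SSS........................
.......................SSS........................
..........LLLLLLLLLLLLL...R.......................
.........L.................R......................
........L...................R.....................
........L....................R....................
........L....................R....................
........L....................R....................
........L....................R....................
........L....................R....................
........L....................R....................
........L....................R....................
........L....................R....................
........L....................R....................
........L....................R....................
........LLLLL................R....................
............L................R....................
............L................R....................
............L................R....................
............L................R....................
........LLLLL................R....................
........L....................R....................
........L....................R....................
........L....................R....................
........L....................R....................
........L....................R....................
........L....................R....................
........L....................R....................
........L....................R....................
........LLLLLLLLLLL..........R....................
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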