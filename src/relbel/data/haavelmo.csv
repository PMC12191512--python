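year,income,investment
1922,433,39
1923,483,60
1924,479,42
1925,486,52
1926,494,47
1927,498,51
1928,511,45
1929,534,60
1930,478,39
1931,440,41
1932,372,22
1933,381,17
1934,419,27
1935,449,33
1936,511,48
1937,520,51
1938,477,33
1939,517,46
1940,548,54
1941,629,100
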