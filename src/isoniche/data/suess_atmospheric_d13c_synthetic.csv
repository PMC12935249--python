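year,d13C_atm_permil
1850,-6.4943
1851,-6.4957
1852,-6.4972
1853,-6.4987
1854,-6.5002
1855,-6.5018
1856,-6.5034
1857,-6.505
1858,-6.5067
1859,-6.5084
1860,-6.5101
1861,-6.5119
1862,-6.5137
1863,-6.5156
1864,-6.5175
1865,-6.5194
1866,-6.5214
1867,-6.5234
1868,-6.5255
1869,-6.5276
1870,-6.5298
1871,-6.532
1872,-6.5342
1873,-6.5365
1874,-6.5389
1875,-6.5413
1876,-6.5438
1877,-6.5463
1878,-6.5489
1879,-6.5515
1880,-6.5542
1881,-6.5569
1882,-6.5597
1883,-6.5626
1884,-6.5655
1885,-6.5685
1886,-6.5716
1887,-6.5747
1888,-6.5779
1889,-6.5812
1890,-6.5845
1891,-6.5879
1892,-6.5914
1893,-6.595
1894,-6.5986
1895,-6.6023
1896,-6.6061
1897,-6.61
1898,-6.614
1899,-6.6181
1900,-6.6222
1901,-6.6264
1902,-6.6308
1903,-6.6352
1904,-6.6397
1905,-6.6443
1906,-6.6491
1907,-6.6539
1908,-6.6588
1909,-6.6639
1910,-6.669
1911,-6.6743
1912,-6.6797
1913,-6.6852
1914,-6.6908
1915,-6.6965
1916,-6.7024
1917,-6.7084
1918,-6.7145
1919,-6.7208
1920,-6.7272
1921,-6.7337
1922,-6.7404
1923,-6.7473
1924,-6.7542
1925,-6.7614
1926,-6.7687
1927,-6.7761
1928,-6.7837
1929,-6.7915
1930,-6.7995
1931,-6.8076
1932,-6.8159
1933,-6.8244
1934,-6.8331
1935,-6.8419
1936,-6.851
1937,-6.8602
1938,-6.8697
1939,-6.8794
1940,-6.8892
1941,-6.8993
1942,-6.9097
1943,-6.9202
1944,-6.931
1945,-6.942
1946,-6.9532
1947,-6.9647
1948,-6.9765
1949,-6.9885
1950,-7.0008
1951,-7.0133
1952,-7.0261
1953,-7.0392
1954,-7.0526
1955,-7.0663
1956,-7.0803
1957,-7.0946
1958,-7.1092
1959,-7.1241
1960,-7.1394
1961,-7.1549
1962,-7.1709
1963,-7.1871
1964,-7.2038
1965,-7.2208
1966,-7.2381
1967,-7.2559
1968,-7.274
1969,-7.2926
1970,-7.3115
1971,-7.3309
1972,-7.3506
1973,-7.3709
1974,-7.3915
1975,-7.4126
1976,-7.4342
1977,-7.4563
1978,-7.4788
1979,-7.5018
1980,-7.5254
1981,-7.5494
1982,-7.574
1983,-7.5991
1984,-7.6248
1985,-7.651
1986,-7.6778
1987,-7.7052
1988,-7.7332
1989,-7.7618
1990,-7.7911
1991,-7.8209
1992,-7.8515
1993,-7.8827
1994,-7.9146
1995,-7.9472
1996,-7.9805
1997,-8.0145
1998,-8.0493
1999,-8.0848
2000,-8.1212
2001,-8.1583
2002,-8.1962
2003,-8.235
2004,-8.2746
2005,-8.3151
2006,-8.3565
2007,-8.3987
2008,-8.442
2009,-8.4861
2010,-8.5312
2011,-8.5774
2012,-8.6245
2013,-8.6727
2014,-8.7219
2015,-8.7722
2016,-8.8236
2017,-8.8761
2018,-8.9298
2019,-8.9846
2020,-9.0407
2021,-9.098
2022,-9.1566
2023,-9.2164
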